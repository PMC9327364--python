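"""Synthetic fraction-resolved RNA-seq data with known ground truth.

Emulates a two-condition (control vs oxidative stress) x two-fraction
(nuclear vs cytoplasmic) design with replicated libraries: negative-binomial
counts, a planted minority of fraction-asymmetric transcripts, retention-motif
insertions enriched among nuclear-planted transcripts, and planted A-to-G
edits and SNPs with pileup-style base-call evidence. Every downstream stage of
the pipeline can be exercised against the returned :class:`SyntheticTruth`.

Counts follow NB(mean mu, variance mu + alpha*mu^2) with a shared dispersion
alpha by default. Fraction asymmetry of magnitude ``planted_log2fc`` is split
symmetrically in log space around a transcript's base abundance, so a
transcript's total abundance is independent of its localization category.
Per-sample library sizes are drawn log-normally around ``library_size_mean``
to exercise normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import SampleDesign
from .motifs import MotifDefinition, concrete_realization, motif_length

CATEGORIES = ("nuclear", "cytoplasmic", "mixed", "unexpressed")

# Mostly-retained classification between conditions, with the mixed pool
# feeding the localized classes under stress (the dominant transition pattern
# in fraction-resolved stress experiments).
DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    "nuclear": {"nuclear": 0.92, "mixed": 0.06, "cytoplasmic": 0.0, "unexpressed": 0.02},
    "cytoplasmic": {"cytoplasmic": 0.92, "mixed": 0.06, "nuclear": 0.0, "unexpressed": 0.02},
    "mixed": {"mixed": 0.82, "nuclear": 0.10, "cytoplasmic": 0.05, "unexpressed": 0.03},
    "unexpressed": {"unexpressed": 0.95, "mixed": 0.05, "nuclear": 0.0, "cytoplasmic": 0.0},
}

DEFAULT_MOTIF_RATES: dict[str, float] = {
    "nuclear": 0.60,
    "cytoplasmic": 0.10,
    "mixed": 0.15,
    "unexpressed": 0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study. ``seed`` fully determines all outputs."""

    n_transcripts: int = 2000
    transcript_length_range: tuple[int, int] = (400, 3000)
    n_replicates: int = 5
    conditions: tuple[str, ...] = ("control", "H2O2")
    fractions: tuple[str, ...] = ("nuclear", "cytoplasmic")
    frac_nuclear_planted: float = 0.10
    frac_cytoplasmic_planted: float = 0.05
    frac_mixed_planted: float = 0.65
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    library_size_mean: float = 2e6
    library_size_sigma: float = 0.15
    expressed_rpkm_log_mean: float = np.log(15.0)
    expressed_rpkm_log_sigma: float = 1.0
    expressed_rpkm_min: float = 2.0
    unexpressed_rpkm_range: tuple[float, float] = (0.02, 0.30)
    transition_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_TRANSITIONS
    )
    motif_insertion_rate_by_category: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_MOTIF_RATES
    )
    edit_rate: float = 0.05
    snp_rate: float = 0.02
    coverage_mean: float = 30.0
    alt_fraction: float = 0.5
    error_rate: float = 0.001
    edited_fraction_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # nuclear-only, cyto-only, both
    n_background_pileup_transcripts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        props = (self.frac_nuclear_planted, self.frac_cytoplasmic_planted, self.frac_mixed_planted)
        if any(p < 0 or p > 1 for p in props):
            raise ValueError("planted proportions must lie in [0, 1]")
        if sum(props) > 1 + 1e-12:
            raise ValueError("planted proportions sum to more than 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (dispersion undefined otherwise)")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.alt_fraction <= self.error_rate:
            raise ValueError("alt_fraction must exceed error_rate (edits undetectable by construction)")
        lo, hi = self.transcript_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid transcript_length_range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,)))

    @property
    def frac_unexpressed(self) -> float:
        return 1.0 - (
            self.frac_nuclear_planted + self.frac_cytoplasmic_planted + self.frac_mixed_planted
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: categories, motif placements, edit and SNP sites."""

    category: pd.DataFrame  # transcripts x conditions, values in CATEGORIES
    lengths: pd.Series
    motif_placements: list[tuple[str, str, int]] = field(default_factory=list)
    edit_sites: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)
    snp_sites: list[tuple[str, int]] = field(default_factory=list)

    def transcripts_in(self, condition: str, category: str) -> list[str]:
        col = self.category[condition]
        return list(col.index[col == category])

    def placements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.motif_placements, columns=["transcript_id", "motif", "offset"])

    def edit_sites_frame(self) -> pd.DataFrame:
        rows = [(t, p, ";".join(fr)) for t, p, fr in self.edit_sites]
        return pd.DataFrame(rows, columns=["transcript_id", "pos0", "fractions"])

    def snp_sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.snp_sites, columns=["transcript_id", "pos0"])


def _draw_categories(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    p = np.array(
        [
            config.frac_nuclear_planted,
            config.frac_cytoplasmic_planted,
            config.frac_mixed_planted,
            config.frac_unexpressed,
        ]
    )
    p = np.clip(p, 0, None)
    p = p / p.sum()
    return rng.choice(np.array(CATEGORIES), size=config.n_transcripts, p=p)


def _transition(rng: np.random.Generator, config: SyntheticConfig, base: np.ndarray) -> np.ndarray:
    out = np.empty_like(base)
    for cat in CATEGORIES:
        idx = np.where(base == cat)[0]
        if len(idx) == 0:
            continue
        probs = config.transition_probs.get(cat, {cat: 1.0})
        cats = list(probs)
        p = np.array([probs[c] for c in cats], dtype=float)
        p = p / p.sum()
        out[idx] = rng.choice(np.array(cats), size=len(idx), p=p)
    return out


def simulate_counts(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SampleDesign, SyntheticTruth]:
    """Draw the count matrix, sample design, and planted truth.

    Returns integer counts (transcripts x samples), the design mapping each
    sample to (condition, fraction, replicate), and the truth table. The
    fraction-mean ratio for planted transcripts equals 2**(+-planted_log2fc)
    (cytoplasm:nuclear orientation) and 1 for mixed transcripts; unexpressed
    transcripts sit below 0.5 expected RPKM everywhere.
    """
    rng = config.rng(0)
    n = config.n_transcripts
    ids = [f"TX{i:05d}" for i in range(n)]
    lo, hi = config.transcript_length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, size=n), index=ids, name="length_bp")

    base_cats = _draw_categories(rng, config)
    cat_cols = {config.conditions[0]: base_cats}
    for cond in config.conditions[1:]:
        cat_cols[cond] = _transition(rng, config, base_cats)
    category = pd.DataFrame(cat_cols, index=ids)

    # Base abundance in RPKM units. Unexpressed levels are fixed below the
    # 0.5 filter; expressed levels are scaled so total expected counts match
    # the drawn library size (sum over transcripts of rpkm*length = 1e9).
    expressed_level = np.maximum(
        rng.lognormal(config.expressed_rpkm_log_mean, config.expressed_rpkm_log_sigma, size=n),
        config.expressed_rpkm_min,
    )
    unexpressed_level = rng.uniform(*config.unexpressed_rpkm_range, size=n)

    len_arr = lengths.to_numpy(float)
    design_rows = []
    mu_cols = {}
    half = 0.5 * config.planted_log2fc
    for cond in config.conditions:
        cats = category[cond].to_numpy()
        unexpr = cats == "unexpressed"
        level = np.where(unexpr, unexpressed_level, expressed_level)
        # budget: expressed transcripts absorb what the unexpressed leave over
        budget = 1e9 - float((level[unexpr] * len_arr[unexpr]).sum())
        expr_total = float((level[~unexpr] * len_arr[~unexpr]).sum())
        scale = budget / expr_total if expr_total > 0 else 1.0
        level = np.where(unexpr, level, level * scale)
        # symmetric split of the asymmetry in log2 space
        shift = np.zeros(n)
        shift[cats == "cytoplasmic"] = half
        shift[cats == "nuclear"] = -half
        level_by_frac = {
            "cytoplasmic_like": level * 2.0**shift,
            "nuclear_like": level * 2.0**-shift,
        }
        for frac in config.fractions:
            key = "nuclear_like" if frac == config.fractions[0] else "cytoplasmic_like"
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{cond}_{frac}_rep{rep}"
                design_rows.append(
                    {"sample_id": sample_id, "condition": cond, "fraction": frac, "replicate": rep}
                )
                lib = config.library_size_mean * rng.lognormal(
                    -0.5 * config.library_size_sigma**2, config.library_size_sigma
                )
                mu = level_by_frac[key] * len_arr * lib / 1e9
                alpha = config.nb_dispersion
                # NB(mean mu, var mu + alpha mu^2): n=1/alpha, p = 1/(1+alpha*mu)
                counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
                mu_cols[sample_id] = counts

    counts = pd.DataFrame(mu_cols, index=ids, dtype=np.int64)
    design = SampleDesign(pd.DataFrame(design_rows))
    truth = SyntheticTruth(category=category, lengths=lengths)
    return counts, design, truth


def simulate_sequences(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    motifs: Sequence[MotifDefinition],
    max_retries: int = 50,
) -> dict[str, str]:
    """Uniform-background transcript sequences with planted motif occurrences.

    For each transcript and each motif, a concrete realization of the IUPAC
    pattern is inserted with the category-specific probability (category taken
    from the first condition's truth). Overlapping placements are re-drawn;
    after ``max_retries`` failed draws the transcript errors out. Placements
    are recorded in ``truth.motif_placements``.
    """
    rng = config.rng(1)
    min_len = int(truth.lengths.min())
    for m in motifs:
        if motif_length(m.pattern) > min_len:
            raise ValueError(f"motif {m.name} longer than shortest transcript")

    base_cond = truth.category.columns[0]
    alphabet = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    truth.motif_placements.clear()
    rates = config.motif_insertion_rate_by_category
    for tx in truth.lengths.index:
        L = int(truth.lengths[tx])
        seq = rng.choice(alphabet, size=L)
        cat = truth.category.loc[tx, base_cond]
        occupied: list[tuple[int, int]] = []
        for m in motifs:
            rate = rates.get(cat, 0.0)
            if rng.random() >= rate:
                continue
            mlen = motif_length(m.pattern)
            realization = concrete_realization(m.pattern, rng)
            placed = False
            for _ in range(max_retries):
                off = int(rng.integers(0, L - mlen + 1))
                if all(off + mlen <= s or off >= e for s, e in occupied):
                    seq[off : off + mlen] = list(realization)
                    occupied.append((off, off + mlen))
                    truth.motif_placements.append((tx, m.name, off))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(f"could not place motif {m.name} in {tx} after {max_retries} tries")
        sequences[tx] = "".join(seq)
    return sequences


def plant_variant_sites(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    sequences: Mapping[str, str],
) -> None:
    """Choose edit and SNP sites at reference-A positions, updating the truth.

    Each transcript is independently selected as edited with probability
    ``edit_rate`` and as SNP-bearing with probability ``snp_rate`` (one site
    each, at distinct A positions). Edited fractions are drawn from
    ``edited_fraction_probs`` (nuclear-only / cytoplasmic-only / both).
    Unexpressed-everywhere transcripts are skipped: they carry no read
    evidence to recover.
    """
    rng = config.rng(2)
    truth.edit_sites.clear()
    truth.snp_sites.clear()
    nuc, cyt = config.fractions[0], config.fractions[1]
    frac_choices = [(nuc,), (cyt,), (nuc, cyt)]
    p_frac = np.array(config.edited_fraction_probs, dtype=float)
    p_frac = p_frac / p_frac.sum()
    for tx, seq in sequences.items():
        if (truth.category.loc[tx] == "unexpressed").all():
            continue
        a_pos = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A"))
        if len(a_pos) < 2:
            continue
        want_edit = rng.random() < config.edit_rate
        want_snp = rng.random() < config.snp_rate
        if not (want_edit or want_snp):
            continue
        chosen = rng.choice(a_pos, size=2, replace=False)
        if want_edit:
            which = int(rng.choice(3, p=p_frac))
            truth.edit_sites.append((tx, int(chosen[0]), frac_choices[which]))
        if want_snp:
            truth.snp_sites.append((tx, int(chosen[1])))


def simulate_editing_evidence(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    sequences: Mapping[str, str],
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Per-fraction pileup evidence plus the matched genomic sequences.

    At planted edit sites the transcriptomic calls carry G at ``alt_fraction``
    in the edited fraction(s) while the genomic base stays A; at planted SNP
    sites the genomic sequence carries G and transcriptomic calls are ~all G
    in both fractions (homozygous variant). Elsewhere calls follow the
    reference up to ``error_rate``. Pileups cover transcripts with planted
    sites plus ``n_background_pileup_transcripts`` event-free transcripts.
    """
    rng = config.rng(3)
    bases = "ACGT"
    edit_by_tx: dict[str, list[tuple[int, tuple[str, ...]]]] = {}
    for tx, pos, fracs in truth.edit_sites:
        edit_by_tx.setdefault(tx, []).append((pos, fracs))
    snp_by_tx: dict[str, list[int]] = {}
    for tx, pos in truth.snp_sites:
        snp_by_tx.setdefault(tx, []).append(pos)

    event_txs = sorted(set(edit_by_tx) | set(snp_by_tx))
    background = [tx for tx in sequences if tx not in set(event_txs)]
    n_bg = min(config.n_background_pileup_transcripts, len(background))
    bg_txs = list(rng.choice(np.array(background), size=n_bg, replace=False)) if n_bg else []
    covered = event_txs + sorted(bg_txs)

    genomic = dict(sequences)
    for tx, positions in snp_by_tx.items():
        s = list(genomic[tx])
        for p in positions:
            s[p] = "G"
        genomic[tx] = "".join(s)

    pileups: dict[str, pd.DataFrame] = {}
    for frac in config.fractions:
        frames = []
        for tx in covered:
            seq = sequences[tx]
            L = len(seq)
            cov = rng.poisson(config.coverage_mean, size=L)
            ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
            calls = np.zeros((L, 4), dtype=np.int64)
            # sequencing errors spread uniformly over the three non-ref bases
            errors = rng.binomial(cov, config.error_rate)
            correct = cov - errors
            for bi, b in enumerate(bases):
                is_ref = ref_idx == ord(b)
                calls[is_ref, bi] += correct[is_ref]
            for i in np.flatnonzero(errors):
                alt_slots = [bi for bi, b in enumerate(bases) if b != seq[i]]
                alloc = rng.multinomial(errors[i], [1 / 3] * 3)
                for slot, cnt in zip(alt_slots, alloc):
                    calls[i, slot] += cnt
            for pos, fracs in edit_by_tx.get(tx, []):
                if frac in fracs:
                    g = rng.binomial(calls[pos].sum(), config.alt_fraction)
                    total = calls[pos].sum()
                    calls[pos] = 0
                    calls[pos, bases.index("G")] = g
                    calls[pos, bases.index("A")] = total - g
            for pos in snp_by_tx.get(tx, []):
                total = calls[pos].sum()
                calls[pos] = 0
                calls[pos, bases.index("G")] = total  # homozygous variant: reads all G
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": tx,
                        "pos0": np.arange(L),
                        "ref_base": list(seq),
                        "A": calls[:, 0],
                        "C": calls[:, 1],
                        "G": calls[:, 2],
                        "T": calls[:, 3],
                    }
                )
            )
        pileups[frac] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["transcript_id", "pos0", "ref_base", "A", "C", "G", "T"])
        )
    return pileups, genomic
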