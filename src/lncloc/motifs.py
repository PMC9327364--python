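"""Nuclear-retention motif scanning, random-motif nulls, and enrichment summaries.

Motifs are IUPAC patterns scanned on the sense strand of transcript sequences,
counting overlapping occurrences. Random-motif controls preserve each parent
position's length and purine/pyrimidine/degeneracy structure, so any apparent
enrichment of the real motif can be compared against sequence-composition
artefacts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .localization import CategorySummary, LocalizationResult, summarize_categories

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
PURINES = set("AG")
PYRIMIDINES = set("CT")


@dataclass(frozen=True)
class MotifDefinition:
    """A named IUPAC pattern with provenance (real motif or randomized null)."""

    name: str
    pattern: str
    provenance: str = "real"  # "real" | "randomized"
    source_note: str = ""
    parent: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern {self.pattern!r}: {bad}")
        if self.provenance not in ("real", "randomized"):
            raise ValueError("provenance must be 'real' or 'randomized'")


@dataclass
class MotifHitSummary:
    transcript_id: str
    motif: str
    hit_count: int

    @property
    def has_motif(self) -> bool:
        return self.hit_count >= 1


@dataclass
class TrendResult:
    """OLS fit of log2 cytoplasm:nuclear fold change on per-transcript motif count.

    Nuclear association corresponds to a negative slope in this orientation.
    ``slope``/``r`` are None when the motif count has zero variance.
    """

    motif: str
    condition: str
    slope: float | None
    intercept: float | None
    r: float | None
    n: int


def motif_length(pattern: str) -> int:
    return len(pattern)


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    # N in the pattern matches any of ACGT but an N in the *sequence* matches nothing
    parts = [f"[{IUPAC[c]}]" for c in pattern.upper()]
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(sequence: str, motif: MotifDefinition) -> list[int]:
    """All start offsets where the IUPAC pattern matches, overlapping included."""
    seq = sequence.upper()
    for i, c in enumerate(seq):
        if c not in "ACGTN":
            raise ValueError(f"invalid character {c!r} at position {i}")
    return [m.start() for m in _iupac_regex(motif.pattern).finditer(seq)]


def scan_transcripts(
    sequences: Mapping[str, str], motif: MotifDefinition
) -> pd.DataFrame:
    """Hit counts per transcript: columns transcript_id, motif, hit_count, has_motif."""
    rows = []
    for tx, seq in sequences.items():
        n = len(scan_motif(seq, motif))
        rows.append({"transcript_id": tx, "motif": motif.name, "hit_count": n, "has_motif": n >= 1})
    return pd.DataFrame(rows)


def concrete_realization(pattern: str, rng: np.random.Generator) -> str:
    """One concrete ACGT string drawn uniformly from an IUPAC pattern."""
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in pattern.upper())


def _position_choices(code: str) -> list[str]:
    """IUPAC codes sharing the parent position's structure class."""
    opts = IUPAC[code]
    if len(opts) == 1:
        return ["A", "G"] if code in PURINES else ["C", "T"]
    if len(opts) == 2:
        if set(opts) <= PURINES:
            return ["R"]
        if set(opts) <= PYRIMIDINES:
            return ["Y"]
        return ["S", "W", "K", "M"]
    if len(opts) == 3:
        return ["B", "D", "H", "V"]
    return ["N"]


def structure_space_size(pattern: str) -> int:
    size = 1
    for c in pattern.upper():
        size *= len(_position_choices(c))
    return size


def random_motif_variants(
    motif: MotifDefinition, n: int, seed: int
) -> list[MotifDefinition]:
    """Random same-length, same-structure variants of a motif.

    Each position keeps its class: a fixed purine stays a purine base, a fixed
    pyrimidine a pyrimidine base, and a degenerate IUPAC position keeps its
    cardinality (R/Y are their class's only 2-base codes and stay fixed).
    Variants are drawn uniformly over that space, rejecting the parent itself;
    draws are independent, so a variant may repeat across the list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    parent = motif.pattern.upper()
    if structure_space_size(parent) <= 1:
        raise ValueError(f"motif {motif.name} admits no distinct structure-preserving variant")
    rng = np.random.default_rng(seed)
    choices = [_position_choices(c) for c in parent]
    out = []
    for i in range(n):
        while True:
            variant = "".join(ch[int(rng.integers(len(ch)))] for ch in choices)
            if variant != parent:
                break
        out.append(
            MotifDefinition(
                name=f"{motif.name}_rand{i+1}",
                pattern=variant,
                provenance="randomized",
                source_note=f"structure-preserving randomization of {motif.name}",
                parent=motif.name,
                seed=seed,
            )
        )
    return out


def stratified_distribution(
    results: Iterable[LocalizationResult],
    hits: pd.DataFrame,
    motif: str,
    condition: str,
) -> tuple[CategorySummary, CategorySummary]:
    """Category summaries for transcripts with vs without the motif."""
    res = [r for r in results if r.condition == condition]
    h = hits[hits["motif"] == motif]
    with_set = set(h.loc[h["has_motif"], "transcript_id"])
    known = set(h["transcript_id"])
    missing = {r.transcript_id for r in res} - known
    if missing:
        raise ValueError(f"hits table does not cover {len(missing)} tested transcripts")
    with_summary = summarize_categories([r for r in res if r.transcript_id in with_set], condition)
    without_summary = summarize_categories([r for r in res if r.transcript_id not in with_set], condition)
    return with_summary, without_summary


def motif_count_trend(
    results: Iterable[LocalizationResult],
    hits: pd.DataFrame,
    motif: str,
    condition: str,
) -> TrendResult:
    """Least-squares trend of localization fold change against motif count."""
    res = {r.transcript_id: r.log2fc for r in results if r.condition == condition and np.isfinite(r.log2fc)}
    h = hits[hits["motif"] == motif].set_index("transcript_id")["hit_count"]
    common = [tx for tx in res if tx in h.index]
    if len(common) < 3:
        raise ValueError("need at least 3 transcripts with finite log2fc and hit counts")
    x = h.loc[common].to_numpy(float)
    y = np.array([res[tx] for tx in common])
    if np.allclose(x, x[0]):
        return TrendResult(motif=motif, condition=condition, slope=None, intercept=None, r=None, n=len(common))
    fit = stats.linregress(x, y)
    return TrendResult(
        motif=motif,
        condition=condition,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=len(common),
    )


def load_motif_config(path: str | None = None) -> list[MotifDefinition]:
    """Load motif definitions from YAML (default: the packaged retention motifs)."""
    if path is None:
        text = resources.files("lncloc.data").joinpath("motifs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = yaml.safe_load(text)
    return [
        MotifDefinition(
            name=e["name"],
            pattern=e["pattern"],
            provenance=e.get("provenance", "real"),
            source_note=e.get("source_note", ""),
        )
        for e in entries
    ]
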