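"""A-to-I editing site calling with edit/SNP discrimination.

Inosine is read by sequencers as guanosine, so candidate edits appear as A->G
mismatches in transcriptomic base calls. A candidate becomes a bona fide edit
only when the matched genomic sequence still carries the reference A; if the
genomic base itself differs, the site is a SNP, and with no genomic evidence
the verdict is no_evidence. Sense-strand coordinates throughout: minus-strand
genes must be delivered already reverse-complemented into transcript space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 10
DEFAULT_MIN_ALT_FRACTION = 0.1
DEFAULT_MIN_ALT_READS = 3

VERDICTS = ("edit", "snp", "no_evidence")


@dataclass
class EditingSite:
    """One candidate site with its base-call evidence and verdict."""

    transcript_id: str
    pos0: int
    ref_base: str
    calls: dict[str, int]  # A/C/G/T read counts
    fraction: str
    genomic_base: str | None = None
    verdict: str = "no_evidence"

    @property
    def coverage(self) -> int:
        return sum(self.calls.values())

    @property
    def alt_fraction(self) -> float:
        cov = self.coverage
        return self.calls.get("G", 0) / cov if cov else 0.0


@dataclass
class EditedTranscriptSummary:
    """Edited-transcript sets per fraction and their overlap with localization."""

    condition: str
    edited_by_fraction: dict[str, set[str]]
    localized_by_fraction: dict[str, set[str]]
    overlap_mode: str = "any"

    def edited_count(self, fraction: str) -> int:
        return len(self.edited_by_fraction.get(fraction, set()))

    def overlap(self, fraction: str) -> set[str]:
        return self.edited_by_fraction.get(fraction, set()) & self.localized_by_fraction.get(
            fraction, set()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for frac in sorted(set(self.edited_by_fraction) | set(self.localized_by_fraction)):
            rows.append(
                {
                    "condition": self.condition,
                    "fraction": frac,
                    "n_edited": self.edited_count(frac),
                    "n_localized": len(self.localized_by_fraction.get(frac, set())),
                    "n_localized_and_edited": len(self.overlap(frac)),
                }
            )
        return pd.DataFrame(rows)


def call_sites(
    pileup: pd.DataFrame,
    reference: Mapping[str, str],
    fraction: str = "",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> list[EditingSite]:
    """Candidate A->G sites from pileup evidence.

    A row is a candidate when the reference base is A, G reads >=
    ``min_alt_reads``, G/(A+C+G+T) >= ``min_alt_fraction``, and total coverage
    >= ``min_coverage``. Non-A->G mismatches never become candidates. The
    pileup's ref_base column must agree with the reference sequence.
    """
    required = {"transcript_id", "pos0", "ref_base", "A", "C", "G", "T"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup missing columns: {sorted(missing)}")

    sites: list[EditingSite] = []
    base_cols = ["A", "C", "G", "T"]
    for row in pileup.itertuples(index=False):
        tx = str(row.transcript_id)
        pos = int(row.pos0)
        if tx not in reference:
            raise ValueError(f"transcript {tx} absent from reference sequences")
        seq = reference[tx]
        if pos >= len(seq):
            raise ValueError(f"position {pos} outside {tx} (length {len(seq)})")
        ref_seq_base = seq[pos].upper()
        if str(row.ref_base).upper() != ref_seq_base:
            raise ValueError(
                f"pileup/reference disagreement at {tx}:{pos}: "
                f"pileup says {row.ref_base!r}, sequence says {ref_seq_base!r}"
            )
        if ref_seq_base != "A":
            continue
        calls = {b: int(getattr(row, b)) for b in base_cols}
        total = sum(calls.values())
        g = calls["G"]
        if total >= min_coverage and g >= min_alt_reads and total > 0 and g / total >= min_alt_fraction:
            sites.append(
                EditingSite(
                    transcript_id=tx,
                    pos0=pos,
                    ref_base="A",
                    calls=calls,
                    fraction=fraction,
                )
            )
    return sites


def mismatch_class_counts(pileup: pd.DataFrame) -> pd.DataFrame:
    """Read counts per ref->alt mismatch class (bookkeeping; only A->G can
    ever become an edit candidate)."""
    rows: dict[tuple[str, str], int] = {}
    for row in pileup.itertuples(index=False):
        ref = str(row.ref_base).upper()
        for alt in "ACGT":
            if alt == ref:
                continue
            n = int(getattr(row, alt))
            if n:
                rows[(ref, alt)] = rows.get((ref, alt), 0) + n
    out = [{"ref": r, "alt": a, "reads": n} for (r, a), n in sorted(rows.items())]
    return pd.DataFrame(out, columns=["ref", "alt", "reads"])


def discriminate_snps(
    candidates: Iterable[EditingSite], genomic: Mapping[str, str]
) -> list[EditingSite]:
    """Assign edit/snp/no_evidence verdicts from the matched genomic sequence.

    Genomic base equal to the reference A => bona fide edit; a genomic base
    that differs => SNP; missing or ambiguous genomic coverage => no_evidence.
    """
    out = []
    for site in candidates:
        seq = genomic.get(site.transcript_id)
        if seq is None or site.pos0 >= len(seq) or seq[site.pos0].upper() == "N":
            logger.warning(
                "no genomic evidence for %s:%d; verdict no_evidence",
                site.transcript_id,
                site.pos0,
            )
            site.genomic_base = None
            site.verdict = "no_evidence"
        else:
            gbase = seq[site.pos0].upper()
            site.genomic_base = gbase
            site.verdict = "edit" if gbase == site.ref_base else "snp"
        out.append(site)
    return out


def edited_transcripts(sites: Iterable[EditingSite]) -> set[str]:
    """Transcripts with at least one bona fide edit verdict."""
    return {s.transcript_id for s in sites if s.verdict == "edit"}


def editing_localization_overlap(
    sites_by_fraction: Mapping[str, Sequence[EditingSite]],
    results,
    condition: str,
    mode: str = "any",
) -> EditedTranscriptSummary:
    """Intersect per-fraction edited transcripts with localization categories.

    ``mode='any'``: a transcript is edited in a fraction if it has >= 1 edit
    verdict from that fraction's evidence. ``mode='strict'``: it must also
    have strictly more edit sites in that fraction than in the other(s).
    """
    if mode not in ("any", "strict"):
        raise ValueError("mode must be 'any' or 'strict'")
    edit_counts: dict[str, dict[str, int]] = {}
    for frac, sites in sites_by_fraction.items():
        per_tx: dict[str, int] = {}
        for s in sites:
            if s.verdict == "edit":
                per_tx[s.transcript_id] = per_tx.get(s.transcript_id, 0) + 1
        edit_counts[frac] = per_tx

    edited: dict[str, set[str]] = {}
    for frac, per_tx in edit_counts.items():
        if mode == "any":
            edited[frac] = set(per_tx)
        else:
            others = [f for f in edit_counts if f != frac]
            edited[frac] = {
                tx
                for tx, n in per_tx.items()
                if all(n > edit_counts[o].get(tx, 0) for o in others)
            }

    localized: dict[str, set[str]] = {f: set() for f in edit_counts}
    for r in results:
        if r.condition != condition:
            continue
        if r.category in localized:
            localized[r.category].add(r.transcript_id)
    return EditedTranscriptSummary(
        condition=condition,
        edited_by_fraction=edited,
        localized_by_fraction=localized,
        overlap_mode=mode,
    )


def sites_to_frame(sites: Iterable[EditingSite], one_based: bool = False) -> pd.DataFrame:
    """Tabulate sites; ``one_based=True`` exports VCF-style 1-based positions."""
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "pos" if not one_based else "pos1": s.pos0 + (1 if one_based else 0),
                "ref_base": s.ref_base,
                "A": s.calls.get("A", 0),
                "C": s.calls.get("C", 0),
                "G": s.calls.get("G", 0),
                "T": s.calls.get("T", 0),
                "alt_fraction": round(s.alt_fraction, 6),
                "genomic_base": s.genomic_base if s.genomic_base else ".",
                "fraction": s.fraction,
                "verdict": s.verdict,
            }
        )
    cols = [
        "transcript_id",
        "pos1" if one_based else "pos",
        "ref_base",
        "A",
        "C",
        "G",
        "T",
        "alt_fraction",
        "genomic_base",
        "fraction",
        "verdict",
    ]
    return pd.DataFrame(rows, columns=cols)
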