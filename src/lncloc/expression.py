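"""RPKM normalization and the expressed-transcript filter.

A transcript counts as expressed in a condition when its mean RPKM across all
of that condition's samples (both fractions pooled) exceeds the threshold
(default 0.5, strict inequality). The same rule applied to a single fraction's
replicates gives the per-fraction expressed sets, so both reporting levels of
a fractionation experiment are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RPKM_THRESHOLD = 0.5


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample column to (condition, fraction, replicate).

    The table must have columns sample_id, condition, fraction, replicate;
    sample IDs are unique and every (condition, fraction) cell needs at least
    two replicates for the downstream dispersion estimate to be defined.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample IDs in design: {dupes}")
        sizes = t.groupby(["condition", "fraction"]).size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"fewer than 2 replicates for: {small}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def fractions(self) -> list[str]:
        return list(dict.fromkeys(self.table["fraction"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, condition: str | None = None, fraction: str | None = None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if fraction is not None:
            t = t[t["fraction"] == fraction]
        return list(t["sample_id"])


@dataclass
class ExpressionTable:
    """Per-transcript RPKM plus expressed flags at condition and fraction level."""

    rpkm: pd.DataFrame
    lengths: pd.Series
    mean_rpkm_condition: pd.DataFrame          # transcripts x conditions
    mean_rpkm_fraction: pd.DataFrame           # transcripts x (condition, fraction)
    expressed_condition: pd.DataFrame          # booleans, transcripts x conditions
    expressed_fraction: pd.DataFrame           # booleans, transcripts x (condition, fraction)
    threshold: float = DEFAULT_RPKM_THRESHOLD

    def expressed_set(self, condition: str, fraction: str | None = None) -> set[str]:
        if fraction is None:
            flags = self.expressed_condition[condition]
        else:
            flags = self.expressed_fraction[(condition, fraction)]
        return set(flags.index[flags])

    def counts_summary(self) -> pd.DataFrame:
        """Number of expressed transcripts per condition and per (condition, fraction)."""
        rows = []
        for cond in self.expressed_condition.columns:
            rows.append({"condition": cond, "fraction": "all", "n_expressed": int(self.expressed_condition[cond].sum())})
        for cond, frac in self.expressed_fraction.columns:
            rows.append({"condition": cond, "fraction": frac, "n_expressed": int(self.expressed_fraction[(cond, frac)].sum())})
        return pd.DataFrame(rows)


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million counted reads.

    rpkm[t, s] = counts[t, s] * 1e9 / (length_bp[t] * total_counts[s])
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"lengths missing for transcripts, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e9 / np.outer(lengths.to_numpy(float), totals.to_numpy(float))


def expression_filter(
    rpkm: pd.DataFrame,
    design: SampleDesign,
    lengths: pd.Series | None = None,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> ExpressionTable:
    """Flag transcripts as expressed per condition and per (condition, fraction).

    The condition-level flag pools both fractions (mean over all samples of
    the condition); fraction-level flags average that fraction's replicates
    only. Both use a strict > comparison against the threshold.
    """
    unknown = set(design.sample_ids) - set(rpkm.columns)
    if unknown:
        raise ValueError(f"design references samples absent from the matrix: {sorted(unknown)}")

    mean_cond = {}
    expr_cond = {}
    mean_frac = {}
    expr_frac = {}
    for cond in design.conditions:
        cols = design.samples(condition=cond)
        m = rpkm[cols].mean(axis=1)
        mean_cond[cond] = m
        expr_cond[cond] = m > threshold
        for frac in design.fractions:
            fcols = design.samples(condition=cond, fraction=frac)
            fm = rpkm[fcols].mean(axis=1)
            mean_frac[(cond, frac)] = fm
            expr_frac[(cond, frac)] = fm > threshold

    if lengths is None:
        lengths = pd.Series(np.nan, index=rpkm.index, name="length_bp")
    return ExpressionTable(
        rpkm=rpkm,
        lengths=lengths.reindex(rpkm.index),
        mean_rpkm_condition=pd.DataFrame(mean_cond),
        mean_rpkm_fraction=pd.DataFrame(mean_frac),
        expressed_condition=pd.DataFrame(expr_cond),
        expressed_fraction=pd.DataFrame(expr_frac),
        threshold=threshold,
    )
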