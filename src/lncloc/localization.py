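"""Differential nuclear-vs-cytoplasmic localization testing and classification.

For each condition, cytoplasmic and nuclear replicates are compared with a
two-group negative-binomial Wald test:

* size factors by the median-of-ratios method;
* per-transcript dispersion alpha by method of moments on normalized counts
  (variance mu + alpha*mu^2), floored at 1e-8, then shrunk conservatively by
  taking the maximum of the per-transcript estimate and a fitted
  alpha(mu) = a0 + a1/mu trend;
* Wald statistic on log((cyt_mean + c) / (nuc_mean + c)), pseudocount c = 0.5,
  with a delta-method standard error;
* Benjamini-Hochberg adjustment over all tested transcripts.

Classification follows the two-threshold rule: localized (nuclear or
cytoplasmic) requires at least a two-fold difference with adjusted p < 0.01;
a fold change below 1.9 in either direction is mixed regardless of p; the gap
(ratio in [1.9, 2.0), or >= 2-fold but non-significant) is left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import SampleDesign

logger = logging.getLogger(__name__)

CLASS_CATEGORIES = ("nuclear", "cytoplasmic", "mixed", "unassigned")
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class LocalizationResult:
    """Per-transcript test result, cytoplasm:nuclear orientation (positive
    log2fc means cytoplasmic enrichment)."""

    transcript_id: str
    condition: str
    log2fc: float
    pvalue: float
    padj: float
    category: str


@dataclass
class CategorySummary:
    """Counts and percentages per localization category for one condition.

    Percentages are over classified transcripts (nuclear + cytoplasmic +
    mixed); unassigned transcripts are counted but excluded from the
    percentage denominator.
    """

    condition: str
    counts: dict[str, int]

    @property
    def n_classified(self) -> int:
        return sum(self.counts.get(c, 0) for c in ("nuclear", "cytoplasmic", "mixed"))

    @property
    def localized_total(self) -> int:
        return self.counts.get("nuclear", 0) + self.counts.get("cytoplasmic", 0)

    @property
    def percentages(self) -> dict[str, float]:
        denom = self.n_classified
        if denom == 0:
            return {c: float("nan") for c in ("nuclear", "cytoplasmic", "mixed")}
        return {c: 100.0 * self.counts.get(c, 0) / denom for c in ("nuclear", "cytoplasmic", "mixed")}

    @property
    def empty(self) -> bool:
        return self.n_classified == 0 and self.counts.get("unassigned", 0) == 0

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [
            {
                "condition": self.condition,
                "category": c,
                "count": self.counts.get(c, 0),
                "percent": pct.get(c, float("nan")),
            }
            for c in CLASS_CATEGORIES
        ]
        return pd.DataFrame(rows)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over transcripts with all-positive counts."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts.to_numpy(float))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no transcript has positive counts in every sample; cannot normalize")
    log_ratios = log_counts[usable] - log_geo[usable, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a0 + a1/mu on positive moment estimates."""
    ok = (alpha_hat > 0) & (base_mean > 0) & np.isfinite(alpha_hat)
    if ok.sum() < 10:
        med = float(np.median(alpha_hat[ok])) if ok.any() else DISPERSION_FLOOR
        return max(med, DISPERSION_FLOOR), 0.0
    x = 1.0 / base_mean[ok]
    y = alpha_hat[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0 = max(float(coef[0]), DISPERSION_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def differential_localization(
    counts: pd.DataFrame,
    design: SampleDesign,
    condition: str,
    expressed: Iterable[str] | None = None,
    nuclear_label: str = "nuclear",
    cytoplasmic_label: str = "cytoplasmic",
    pseudocount: float = PSEUDOCOUNT,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """NB Wald test of cytoplasmic vs nuclear replicates within one condition.

    Returns a DataFrame indexed by transcript with columns log2fc, pvalue,
    padj, base_mean, dispersion. Rows with zero counts in every sample are
    excluded (logged); the test is restricted to ``expressed`` transcripts
    when given.
    """
    cyt_cols = design.samples(condition=condition, fraction=cytoplasmic_label)
    nuc_cols = design.samples(condition=condition, fraction=nuclear_label)
    if len(cyt_cols) < 2 or len(nuc_cols) < 2:
        raise ValueError(f"need >= 2 replicates per fraction in condition {condition!r}")
    sub = counts[cyt_cols + nuc_cols]
    if expressed is not None:
        keep = sub.index.intersection(pd.Index(expressed))
        sub = sub.loc[keep]

    all_zero = (sub == 0).all(axis=1)
    if all_zero.any():
        logger.info(
            "excluding %d all-zero transcript(s) in condition %s", int(all_zero.sum()), condition
        )
        sub = sub.loc[~all_zero]
    if sub.empty:
        raise ValueError(f"no testable transcripts in condition {condition!r}")

    sf = size_factors(sub)
    norm = sub / sf
    cyt = norm[cyt_cols].to_numpy(float)
    nuc = norm[nuc_cols].to_numpy(float)
    n_c, n_n = cyt.shape[1], nuc.shape[1]

    mean_c = cyt.mean(axis=1)
    mean_n = nuc.mean(axis=1)
    var_c = cyt.var(axis=1, ddof=1)
    var_n = nuc.var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1).to_numpy(float)

    inv_sf_c = float((1.0 / sf[cyt_cols]).mean())
    inv_sf_n = float((1.0 / sf[nuc_cols]).mean())

    # method-of-moments: alpha = (sample var - shot noise) / mu^2, per group
    with np.errstate(divide="ignore", invalid="ignore"):
        a_c = (var_c - mean_c * inv_sf_c) / mean_c**2
        a_n = (var_n - mean_n * inv_sf_n) / mean_n**2
    a_c = np.where(np.isfinite(a_c), a_c, 0.0)
    a_n = np.where(np.isfinite(a_n), a_n, 0.0)
    w_c, w_n = n_c - 1, n_n - 1
    alpha_hat = (w_c * a_c + w_n * a_n) / (w_c + w_n)
    alpha = np.maximum(alpha_hat, DISPERSION_FLOOR)
    if shrink_dispersion:
        a0, a1 = _fit_dispersion_trend(base_mean, alpha_hat)
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.maximum(base_mean, 1e-12)
        alpha = np.maximum(alpha, trend)

    log2fc = np.log2((mean_c + pseudocount) / (mean_n + pseudocount))

    # delta method: Var(ln(mean_g + c)) ~ Var(mean_g) / (mean_g + c)^2 with
    # Var(mean_g) = mu*mean(1/s)/n + alpha*mu^2/n under the NB model
    var_mean_c = mean_c * inv_sf_c / n_c + alpha * mean_c**2 / n_c
    var_mean_n = mean_n * inv_sf_n / n_n + alpha * mean_n**2 / n_n
    var_ln = var_mean_c / (mean_c + pseudocount) ** 2 + var_mean_n / (mean_n + pseudocount) ** 2
    se_ln = np.sqrt(np.maximum(var_ln, 1e-300))
    wald = np.log((mean_c + pseudocount) / (mean_n + pseudocount)) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "base_mean": base_mean,
            "dispersion": alpha,
        },
        index=sub.index,
    )


def classify(
    log2fc: float,
    padj: float,
    fc_threshold: float = 2.0,
    mixed_threshold: float = 1.9,
    alpha: float = 0.01,
) -> str:
    """Three-way localization call with an explicit unassigned gap.

    cytoplasmic: ratio >= fc_threshold and padj < alpha; nuclear: the same on
    the reciprocal; mixed: max(ratio, 1/ratio) < mixed_threshold regardless of
    significance; everything else (ratio in [1.9, 2.0) or large but
    non-significant) is unassigned.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if not (0.0 <= padj <= 1.0):
        raise ValueError("padj must lie in [0, 1]")
    ratio = 2.0**log2fc
    if ratio >= fc_threshold and padj < alpha:
        return "cytoplasmic"
    if ratio <= 1.0 / fc_threshold and padj < alpha:
        return "nuclear"
    if max(ratio, 1.0 / ratio) < mixed_threshold:
        return "mixed"
    return "unassigned"


def classify_results(
    tested: pd.DataFrame,
    condition: str,
    fc_threshold: float = 2.0,
    mixed_threshold: float = 1.9,
    alpha: float = 0.01,
) -> list[LocalizationResult]:
    """Apply :func:`classify` to a differential_localization result frame."""
    out = []
    for tx, row in tested.iterrows():
        cat = classify(row["log2fc"], row["padj"], fc_threshold, mixed_threshold, alpha)
        out.append(
            LocalizationResult(
                transcript_id=str(tx),
                condition=condition,
                log2fc=float(row["log2fc"]),
                pvalue=float(row["pvalue"]),
                padj=float(row["padj"]),
                category=cat,
            )
        )
    return out


def summarize_categories(
    results: Iterable[LocalizationResult], condition: str | None = None
) -> CategorySummary:
    results = list(results)
    if condition is None:
        condition = results[0].condition if results else ""
    counts = {c: 0 for c in CLASS_CATEGORIES}
    for r in results:
        counts[r.category] += 1
    return CategorySummary(condition=condition, counts=counts)


def fold_increase(count_control: int, count_treated: int) -> float | None:
    """treated/control rounded half-up to one decimal; None for zero control."""
    if count_control == 0:
        return None
    ratio = Decimal(count_treated) / Decimal(count_control)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def transition_table(
    results_control: Iterable[LocalizationResult],
    results_treated: Iterable[LocalizationResult],
    expressed_control: Iterable[str] | None = None,
    expressed_treated: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Category-transition counts over transcripts expressed in both conditions.

    Rows are the control category, columns the treated category; the diagonal
    is retained classification.
    """
    ctrl = {r.transcript_id: r.category for r in results_control}
    trt = {r.transcript_id: r.category for r in results_treated}
    shared = set(ctrl) & set(trt)
    if expressed_control is not None:
        shared &= set(expressed_control)
    if expressed_treated is not None:
        shared &= set(expressed_treated)
    table = pd.DataFrame(0, index=list(CLASS_CATEGORIES), columns=list(CLASS_CATEGORIES), dtype=int)
    for tx in shared:
        table.loc[ctrl[tx], trt[tx]] += 1
    table.index.name = "control"
    table.columns.name = "treated"
    return table
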