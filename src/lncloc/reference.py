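"""Reference category counts from the published iPSC-RPE fractionation study
whose design this package emulates, plus arithmetic consistency checks.

The counts are the study's reported full-scale numbers (which require its
deposited sequencing data to regenerate); here they serve as a fixture for
checking that the summary and fold-increase operations reproduce the
relationships among them: localized totals, fold increases under oxidative
stress, and the >75% nuclear share of localized transcripts at baseline.
"""

from __future__ import annotations

import pandas as pd

from .localization import CategorySummary, fold_increase

# Reported category counts: control vs H2O2-stressed iPSC-RPE.
REFERENCE_COUNTS: dict[str, dict[str, int]] = {
    "control": {"nuclear": 775, "cytoplasmic": 222, "mixed": 3156},
    "H2O2": {"nuclear": 1253, "cytoplasmic": 520, "mixed": 3553},
}

# Expressed-transcript counts (RPKM > 0.5): condition level pools fractions.
REFERENCE_EXPRESSED: dict[str, dict[str, int]] = {
    "control": {"all": 7264, "nuclear": 5993, "cytoplasmic": 5542},
    "H2O2": {"all": 7133, "nuclear": 6294, "cytoplasmic": 5294},
}

# Edited lncRNA transcripts per fraction, and localized-and-edited overlaps.
REFERENCE_EDITED: dict[str, dict[str, int]] = {
    "control": {"nuclear": 115, "cytoplasmic": 74},
    "H2O2": {"nuclear": 74, "cytoplasmic": 102},
}
REFERENCE_LOCALIZED_AND_EDITED: dict[str, dict[str, int]] = {
    "control": {"nuclear": 16, "cytoplasmic": 0},
    "H2O2": {"nuclear": 17, "cytoplasmic": 4},
}


def reference_summary(condition: str) -> CategorySummary:
    """Reference counts wrapped as a CategorySummary (unassigned not reported)."""
    counts = dict(REFERENCE_COUNTS[condition])
    counts["unassigned"] = 0
    return CategorySummary(condition=condition, counts=counts)


def check_reference_arithmetic() -> pd.DataFrame:
    """Recompute the arithmetic relationships among the reference counts.

    Returns a table with one row per check (name, expected, computed, passed):
    localized totals 997 and 1773, nuclear/cytoplasmic fold increases 1.6 and
    2.3, and the baseline nuclear share of localized transcripts > 75%.
    """
    ctrl = reference_summary("control")
    trt = reference_summary("H2O2")
    nuclear_share = 100.0 * ctrl.counts["nuclear"] / ctrl.localized_total

    checks = [
        ("localized_total_control", 997, ctrl.localized_total),
        ("localized_total_H2O2", 1773, trt.localized_total),
        (
            "nuclear_fold_increase",
            1.6,
            fold_increase(ctrl.counts["nuclear"], trt.counts["nuclear"]),
        ),
        (
            "cytoplasmic_fold_increase",
            2.3,
            fold_increase(ctrl.counts["cytoplasmic"], trt.counts["cytoplasmic"]),
        ),
        ("nuclear_share_of_localized_control_gt_75pct", True, nuclear_share > 75.0),
    ]
    rows = [
        {"check": name, "expected": exp, "computed": got, "passed": exp == got}
        for name, exp, got in checks
    ]
    return pd.DataFrame(rows)
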