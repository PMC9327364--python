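import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncloc.expression import SampleDesign
from lncloc.localization import (
    CategorySummary,
    LocalizationResult,
    classify,
    classify_results,
    differential_localization,
    fold_increase,
    summarize_categories,
    transition_table,
)


def _design(conditions=("control",), n_reps=4):
    rows = []
    for cond in conditions:
        for frac in ("nuclear", "cytoplasmic"):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{frac}_{rep}",
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


class TestClassify:
    @pytest.mark.parametrize(
        "ratio, padj, expected",
        [
            (4.9, 0.001, "cytoplasmic"),   # validated cytoplasmic example
            (0.96, 0.5, "mixed"),          # validated mixed example
            (0.96, 0.001, "mixed"),        # mixed regardless of significance
            (0.0005, 0.001, "nuclear"),    # strongly nuclear example
            (1.95, 0.5, "unassigned"),     # the 1.9-2.0 non-significant gap
            (3.0, 0.5, "unassigned"),      # large fold but non-significant
            (2.0, 0.009, "cytoplasmic"),   # boundary: ratio exactly 2
            (1.9, 0.5, "unassigned"),      # boundary: mixed needs ratio < 1.9
        ],
    )
    def test_rule(self, ratio, padj, expected):
        assert classify(np.log2(ratio), padj) == expected

    @given(
        log2fc=st.floats(min_value=-20, max_value=20, allow_nan=False),
        padj=st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_partitions_without_gaps(self, log2fc, padj):
        assert classify(log2fc, padj) in ("nuclear", "cytoplasmic", "mixed", "unassigned")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), 0.5)
        with pytest.raises(ValueError):
            classify(0.0, 1.5)


class TestDifferentialLocalization:
    def test_symmetric_counts_give_null_result(self):
        design = _design()
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=(30, 4))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"t{i}" for i in range(30)],
            columns=design.samples("control", "nuclear") + design.samples("control", "cytoplasmic"),
        )
        res = differential_localization(counts, design, "control")
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_replicate_permutation_invariance(self):
        design = _design()
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(10, 400, size=(25, 8)),
            index=[f"t{i}" for i in range(25)],
            columns=design.sample_ids,
        )
        res1 = differential_localization(counts, design, "control")
        nuc = design.samples("control", "nuclear")
        permuted = counts.rename(columns={nuc[0]: nuc[1], nuc[1]: nuc[0]})[counts.columns]
        res2 = differential_localization(permuted, design, "control")
        pd.testing.assert_frame_equal(res1, res2)

    def test_fraction_swap_negates_log2fc(self):
        design = _design()
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(10, 400, size=(25, 8)),
            index=[f"t{i}" for i in range(25)],
            columns=design.sample_ids,
        )
        res = differential_localization(counts, design, "control")
        swapped_design = SampleDesign(
            design.table.assign(
                fraction=design.table["fraction"].map(
                    {"nuclear": "cytoplasmic", "cytoplasmic": "nuclear"}
                )
            )
        )
        res_sw = differential_localization(counts, swapped_design, "control")
        np.testing.assert_allclose(res["log2fc"], -res_sw["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res["pvalue"], res_sw["pvalue"], atol=1e-12)

    def test_bh_is_monotone_in_pvalue(self):
        design = _design()
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(200, 8)),
            index=[f"t{i}" for i in range(200)],
            columns=design.sample_ids,
        )
        res = differential_localization(counts, design, "control")
        order = res.sort_values("pvalue")
        assert order["padj"].is_monotonic_increasing

    def test_all_zero_rows_excluded(self):
        design = _design()
        counts = pd.DataFrame(
            [[0] * 8, [20, 30, 25, 22, 40, 41, 39, 38]],
            index=["dead", "alive"],
            columns=design.sample_ids,
        )
        res = differential_localization(counts, design, "control")
        assert list(res.index) == ["alive"]

    def test_unknown_condition_rejected(self, planted_run):
        _, counts, design, _ = planted_run
        with pytest.raises(ValueError, match="replicates"):
            differential_localization(counts, design, "no_such_condition")


class TestSummaries:
    def _results(self, spec):
        out = []
        i = 0
        for cat, n in spec.items():
            for _ in range(n):
                out.append(
                    LocalizationResult(f"t{i}", "control", 0.0, 1.0, 1.0, cat)
                )
                i += 1
        return out

    def test_localized_totals(self):
        s = summarize_categories(self._results({"nuclear": 775, "cytoplasmic": 222, "mixed": 10}))
        assert s.localized_total == 997
        s2 = summarize_categories(self._results({"nuclear": 1253, "cytoplasmic": 520}))
        assert s2.localized_total == 1773

    def test_all_mixed(self):
        s = summarize_categories(self._results({"mixed": 7}))
        assert s.localized_total == 0
        assert s.percentages["mixed"] == pytest.approx(100.0)

    def test_percentages_exclude_unassigned(self):
        s = summarize_categories(self._results({"nuclear": 1, "mixed": 1, "unassigned": 8}))
        assert s.percentages["nuclear"] == pytest.approx(50.0)
        assert sum(s.percentages.values()) == pytest.approx(100.0)


class TestFoldIncrease:
    @pytest.mark.parametrize(
        "ctrl, trt, expected",
        [(775, 1253, 1.6), (222, 520, 2.3), (10, 10, 1.0), (8, 10, 1.3)],
    )
    def test_rounding_half_up(self, ctrl, trt, expected):
        assert fold_increase(ctrl, trt) == expected

    def test_zero_control_undefined(self):
        assert fold_increase(0, 5) is None


class TestTransitionTable:
    def _res(self, mapping, condition):
        return [
            LocalizationResult(tx, condition, 0.0, 1.0, 1.0, cat)
            for tx, cat in mapping.items()
        ]

    def test_identical_inputs_are_diagonal(self):
        mapping = {"a": "nuclear", "b": "mixed", "c": "cytoplasmic"}
        t = transition_table(self._res(mapping, "c1"), self._res(mapping, "c2"))
        assert t.to_numpy().sum() == 3
        assert np.trace(t.to_numpy()) == 3

    def test_single_shift_off_diagonal(self):
        ctrl = self._res({"a": "mixed"}, "c1")
        trt = self._res({"a": "nuclear"}, "c2")
        t = transition_table(ctrl, trt)
        assert t.loc["mixed", "nuclear"] == 1
        assert t.to_numpy().sum() == 1

    def test_restricted_to_shared_expressed(self):
        ctrl = self._res({"a": "mixed", "b": "nuclear"}, "c1")
        trt = self._res({"a": "mixed", "b": "nuclear"}, "c2")
        t = transition_table(ctrl, trt, expressed_control=["a"], expressed_treated=["a", "b"])
        assert t.to_numpy().sum() == 1

    def test_row_sums_equal_control_category_counts(self, planted_run, planted_expression):
        cfg, counts, design, truth = planted_run
        res = {}
        for cond in cfg.conditions:
            tested = differential_localization(
                counts, design, cond, planted_expression.expressed_set(cond)
            )
            res[cond] = classify_results(tested, cond)
        shared = planted_expression.expressed_set("control") & planted_expression.expressed_set("H2O2")
        t = transition_table(res["control"], res["H2O2"], shared, shared)
        tested_both = {r.transcript_id for r in res["control"]} & {
            r.transcript_id for r in res["H2O2"]
        } & shared
        ctrl = summarize_categories(
            [r for r in res["control"] if r.transcript_id in tested_both]
        )
        for cat in t.index:
            assert t.loc[cat].sum() == ctrl.counts[cat]
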