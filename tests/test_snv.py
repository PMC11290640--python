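"""SNV screening: partitions, group comparisons, the consensus calling rule,
categorization, and cross-cancer span."""

import numpy as np
import pandas as pd
import pytest

from pgxscreen.io import MutationMatrix, ResponseTable
from pgxscreen.snv import (
    DRIVER_SET,
    GroupComparison,
    ScreeningRule,
    call_biomarkers,
    categorize_by_drug_count,
    compare_groups,
    cross_cancer_span,
    partition_by_driver_set,
    partition_by_gene,
    passes_rule,
)
from pgxscreen.worked_example import GDSC_BRCA_IC50_ROWS, gdsc_brca_ic50_comparisons

STRICT = ScreeningRule("strict")
RELAXED = ScreeningRule("relaxed")


def _mut(df_rows, genes):
    return MutationMatrix(
        pd.DataFrame(df_rows, index=[f"S{i}" for i in range(len(df_rows))],
                     columns=genes)
    )


def _resp_from_values(drug, measure, values_by_sample):
    return ResponseTable(
        pd.DataFrame(
            {
                "sample_id": list(values_by_sample),
                "drug": drug,
                "measure": measure,
                "value": list(values_by_sample.values()),
            }
        )
    )


class TestPartitions:
    def test_single_mutated_sample(self):
        m = _mut([[1, 0], [0, 0], [0, 0], [0, 0]], ["A", "B"])
        mut, unmut = partition_by_driver_set(m, ["A", "B"])
        assert (len(mut), len(unmut)) == (1, 3)

    def test_multimutated_sample_counted_once(self):
        m = _mut([[1, 1, 1], [0, 0, 0]], ["A", "B", "C"])
        mut, unmut = partition_by_driver_set(m, ["A", "B", "C"])
        assert mut == ["S0"] and unmut == ["S1"]

    def test_all_zero_matrix_gives_empty_mutated_group(self):
        m = _mut([[0], [0]], ["A"])
        mut, unmut = partition_by_driver_set(m, ["A"])
        assert mut == [] and len(unmut) == 2

    def test_absent_drivers_warned_and_dropped(self):
        m = _mut([[1], [0]], ["A"])
        with pytest.warns(UserWarning, match="absent"):
            mut, _ = partition_by_driver_set(m, ["A", "NOT_THERE"])
        assert mut == ["S0"]

    def test_empty_intersection_is_error(self):
        m = _mut([[1]], ["A"])
        with pytest.raises(ValueError):
            partition_by_driver_set(m, ["X", "Y"])

    def test_partition_covers_everything_once(self, rng):
        calls = rng.integers(0, 2, (30, 4))
        m = _mut(calls.tolist(), ["A", "B", "C", "D"])
        mut, unmut = partition_by_driver_set(m, ["A", "B", "C", "D"])
        assert sorted(mut + unmut) == sorted(m.sample_ids)
        assert not set(mut) & set(unmut)


class TestCompareGroups:
    def test_identical_groups_no_signal(self):
        vals = {f"M{i}": v for i, v in enumerate([1.0, 2, 3, 4, 5])}
        vals.update({f"U{i}": v for i, v in enumerate([1.0, 2, 3, 4, 5])})
        resp = _resp_from_values("d", "LFC", vals)
        comp = compare_groups(resp, ([f"M{i}" for i in range(5)],
                                     [f"U{i}" for i in range(5)]), "d", "LFC")
        assert comp.p_t > 0.9 and comp.p_w > 0.9 and comp.p_m > 0.9
        assert comp.mean_mut == pytest.approx(comp.mean_unmut)

    def test_one_pooled_sd_shift_detected_by_all_tests(self, rng):
        x = rng.normal(1.0, 1.0, 100)
        y = rng.normal(0.0, 1.0, 100)
        vals = {f"M{i}": v for i, v in enumerate(x)}
        vals.update({f"U{i}": v for i, v in enumerate(y)})
        resp = _resp_from_values("d", "LFC", vals)
        comp = compare_groups(resp, (list(vals)[:100], list(vals)[100:]), "d", "LFC")
        assert max(comp.p_values) < 0.01

    def test_single_mutated_sample_not_evaluable(self):
        vals = {"M0": 1.0, "U0": 2.0, "U1": 3.0, "U2": 4.0}
        resp = _resp_from_values("d", "AUC", vals)
        comp = compare_groups(resp, (["M0"], ["U0", "U1", "U2"]), "d", "AUC")
        assert not comp.evaluable and np.isnan(comp.p_t)


class TestConsensusRule:
    @pytest.mark.parametrize(
        "triple,strict_pass,relaxed_pass",
        [
            ((0.031, 0.032, 0.019), True, True),  # all three < 0.05
            ((0.085, 0.049, 0.009), True, True),  # one < 0.01
            ((0.011, 0.037, 0.157), False, True),  # two < 0.05, none < 0.01
            ((0.05, 0.05, 0.05), False, False),  # boundary: strict inequality
            ((0.005, 0.2, 0.3), True, False),  # strict via <0.01, not relaxed
        ],
    )
    def test_rule_decisions(self, triple, strict_pass, relaxed_pass):
        assert passes_rule(*triple, STRICT) is strict_pass
        assert passes_rule(*triple, RELAXED) is relaxed_pass

    def test_published_validation_rows(self):
        comps = gdsc_brca_ic50_comparisons()
        strict = {c.gene for c in call_biomarkers(comps, STRICT)}
        relaxed = {c.gene for c in call_biomarkers(comps, RELAXED)}
        assert strict == {"ERBB2", "PIK3CA"}
        assert relaxed == {g for g, *_ in GDSC_BRCA_IC50_ROWS}

    def test_monotone_in_p(self, rng):
        """Lowering any p-value never turns a pass into a fail."""
        for rule in (STRICT, RELAXED):
            for _ in range(200):
                p = rng.uniform(0, 0.2, 3)
                if passes_rule(*p, rule):
                    q = p * rng.uniform(0, 1, 3)
                    assert passes_rule(*q, rule)

    def test_strict_implies_relaxed_when_no_very_small_p(self):
        """Over the 0.001-grid of triples with min p >= 0.01, every strict
        pass is a relaxed pass (the strict arm then requires all three
        < 0.05, which implies two < 0.05)."""
        grid = np.arange(0.01, 0.2, 0.001)
        a, b, c = np.meshgrid(grid, grid, grid, indexing="ij", sparse=True)
        strict = ((a < 0.05) & (b < 0.05) & (c < 0.05)) | (
            np.minimum(np.minimum(a, b), c) < 0.01
        )
        relaxed = ((a < 0.05).astype(int) + (b < 0.05) + (c < 0.05)) >= 2
        assert not np.any(strict & ~relaxed)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            ScreeningRule("strict", thresholds=(0.05, 0.05, 0.1))


class TestCallsAndCategories:
    @pytest.mark.parametrize("n,cat", [(1, "1"), (2, "2"), (3, "3+"), (4, "3+")])
    def test_drug_count_category(self, n, cat):
        assert categorize_by_drug_count(n) == cat

    def test_zero_drugs_rejected(self):
        with pytest.raises(ValueError):
            categorize_by_drug_count(0)

    def test_driver_set_excluded_from_calls(self):
        comps = [
            GroupComparison(DRIVER_SET, "d1", "AUC", 10, 10, 1, 0,
                            0.001, 0.001, 0.001),
            GroupComparison("BRAF", "d1", "AUC", 10, 10, 1, 0,
                            0.001, 0.001, 0.001),
        ]
        calls = call_biomarkers(comps, STRICT)
        assert [c.gene for c in calls] == ["BRAF"]

    def test_mixed_measures_rejected(self):
        comps = [
            GroupComparison("A", "d", "AUC", 5, 5, 1, 0, 0.5, 0.5, 0.5),
            GroupComparison("B", "d", "EC50", 5, 5, 1, 0, 0.5, 0.5, 0.5),
        ]
        with pytest.raises(ValueError, match="mix measures"):
            call_biomarkers(comps, STRICT)

    def test_category_reflects_affected_drug_count(self):
        comps = [
            GroupComparison("BRAF", d, "AUC", 10, 10, 1, 0, 0.001, 0.001, 0.001)
            for d in ["d1", "d2", "d3", "d4"]
        ]
        (call,) = call_biomarkers(comps, STRICT)
        assert call.category == "3+" and len(call.affected_drugs) == 4


class TestCrossCancerSpan:
    def _call(self, gene):
        return call_biomarkers(
            [GroupComparison(gene, "d", "AUC", 5, 5, 1, 0, 0.001, 0.001, 0.001)],
            STRICT,
        )

    def test_span_counts_distinct_panels(self):
        calls = {p: self._call("BRAF") for p in ["SKCM", "CRC", "NSCLC", "PRAD"]}
        calls["CML"] = []
        span = cross_cancer_span(calls)
        assert span == {"BRAF": 4}

    def test_two_calls_in_one_panel_span_one(self):
        comps = [
            GroupComparison("G", d, "AUC", 5, 5, 1, 0, 0.001, 0.001, 0.001)
            for d in ("d1", "d2")
        ]
        span = cross_cancer_span({"BRCA": call_biomarkers(comps, STRICT)})
        assert span == {"G": 1}

    def test_sorted_by_span_then_name(self):
        calls = {
            "P1": self._call("ZZZ") + self._call("AAA"),
            "P2": self._call("AAA"),
        }
        span = cross_cancer_span(calls)
        assert list(span) == ["AAA", "ZZZ"]

    def test_empty_input(self):
        assert cross_cancer_span({}) == {}


class TestAdjustmentAndTiers:
    def _comps(self, ps):
        return [
            GroupComparison(f"G{i}", "d", "AUC", 10, 10, 1, 0, p, p, p)
            for i, p in enumerate(ps)
        ]

    def test_bh_adjustment_is_more_conservative(self):
        # two borderline hits in a family of nulls: raw screening calls
        # them, BH (0.04 * 20/2 = 0.4) does not
        ps = [0.04, 0.041] + [0.6 + 0.02 * i for i in range(18)]
        raw = call_biomarkers(self._comps(ps), STRICT)
        adj = call_biomarkers(self._comps(ps), STRICT, bh_adjust=True)
        assert len(raw) == 2 and len(adj) == 0

    def test_bh_keeps_uniformly_strong_signals(self):
        ps = [1e-6] * 5
        adj = call_biomarkers(self._comps(ps), STRICT, bh_adjust=True)
        assert len(adj) == 5

    @pytest.mark.parametrize(
        "triple,tier",
        [
            ((0.005, 0.2, 0.3), "strong"),
            ((0.02, 0.2, 0.3), "moderate"),
            ((0.07, 0.2, 0.3), "weak"),
            ((0.2, 0.5, 0.9), "none"),
        ],
    )
    def test_evidence_tier_ladder(self, triple, tier):
        from pgxscreen.snv import evidence_tier

        assert evidence_tier(*triple) == tier

    def test_weak_tier_never_calls(self):
        assert not passes_rule(0.07, 0.08, 0.09, STRICT)
        assert not passes_rule(0.07, 0.08, 0.09, RELAXED)
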