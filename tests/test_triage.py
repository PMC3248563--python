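"""Tests for the triage decision tree, its stages, and its statistics."""

import numpy as np
import pytest

from wormtriage.errors import (
    IncompleteRecordError,
    PoolingRequiredError,
    UndefinedReductionError,
)
from wormtriage.foci import SuppressionCall
from wormtriage.stats import round_half_away, student_t_test, two_proportion_z_test
from wormtriage.triage import (
    GeneRecord,
    TsOutcome,
    enrichment_chisq,
    functional_class_tally,
    stage_q24_filter,
    stage_q35,
    stage_q35_motility_classes,
    stage_q37_classify,
    stage_sod1,
    stage_ts_rescue,
    stage_wt_motility_filter,
)


def call(gene, positive, strong=False):
    return SuppressionCall(gene, positive, strong, 0.8 if positive else 0.1,
                           30.0 if positive else 95.0)


def record(gene, **kw):
    return GeneRecord(gene_id=gene, **kw)


class TestEarlyStages:
    def test_q35_positive_and_strong_sets(self):
        records = [
            record("a", q35_call=call("a", True, True)),
            record("b", q35_call=call("b", True, True)),
            record("c", q35_call=call("c", True)),
            record("d", q35_call=call("d", False)),
            record("e", q35_call=call("e", False)),
        ]
        positives, strong = stage_q35(records)
        assert positives == {"a", "b", "c"}
        assert strong == {"a", "b"}

    def test_empty_input_gives_empty_sets(self):
        assert stage_q35([]) == (set(), set())

    def test_missing_call_raises(self):
        with pytest.raises(IncompleteRecordError):
            stage_q35([record("a")])

    def test_q24_filter_removes_planted_artifacts(self):
        records = [
            record("a", q24_artifact=True),
            record("b", q24_artifact=False),
            record("c", q24_artifact=True),
        ]
        assert stage_q24_filter(records, {"a", "b", "c"}) == {"a", "c"}
        assert stage_q24_filter(records, {"b"}) == set()

    def test_q37_partition(self):
        records = [
            record("a", q37_call=call("a", True)),
            record("b", q37_call=call("b", False)),
            record("c", q37_call=call("c", True)),
        ]
        class_a, class_b = stage_q37_classify(records, {"a", "b", "c"})
        assert class_a == {"a", "c"}
        assert class_b == {"b"}

    def test_sod1_common_subset(self):
        records = [
            record("a", sod1_call=call("a", True)),
            record("b", sod1_call=call("b", False)),
        ]
        assert stage_sod1(records, {"a", "b"}) == {"a"}
        assert stage_sod1(records, set()) == set()


class TestMotilityStages:
    def setup_method(self):
        rng = np.random.default_rng(99)
        self.control = rng.normal(0.20, 0.05, 75)
        self.q35_control = rng.normal(0.12, 0.04, 75)
        self.rng = rng

    def test_identical_sample_not_excluded(self):
        records = [record("a", wt_blps=self.control.copy())]
        assert stage_wt_motility_filter(records, {"a"}, self.control) == set()

    def test_thirty_percent_slowdown_excluded(self):
        slow = self.rng.normal(0.14, 0.05, 75)
        records = [record("a", wt_blps=slow)]
        assert stage_wt_motility_filter(records, {"a"}, self.control) == {"a"}

    def test_motility_class_directions(self):
        records = [
            record("up", q35_blps=self.rng.normal(0.19, 0.04, 75)),
            record("flat", q35_blps=self.q35_control.copy()),
            record("down", q35_blps=self.rng.normal(0.07, 0.04, 75)),
        ]
        classes, pct = stage_q35_motility_classes(
            records, {"up", "flat", "down"}, self.q35_control
        )
        assert classes == {"up": "suppress", "flat": "no_change", "down": "enhance"}
        assert pct == {"suppress": 33, "no_change": 33, "enhance": 33}

    def test_all_identical_gives_100pct_no_change(self):
        records = [record(f"g{i}", q35_blps=self.q35_control.copy()) for i in range(4)]
        classes, pct = stage_q35_motility_classes(
            records, {f"g{i}" for i in range(4)}, self.q35_control
        )
        assert pct == {"suppress": 0, "no_change": 100, "enhance": 0}

    def test_legend_mode_requires_stricter_alphas(self):
        # borderline: significant at 0.05 but not at the strict legend alpha
        sample = self.q35_control + 0.02
        records = [record("a", q35_blps=sample)]
        single, _ = stage_q35_motility_classes(
            records, {"a"}, self.q35_control, alpha=0.05, mode="single_alpha"
        )
        legend, _ = stage_q35_motility_classes(
            records, {"a"}, self.q35_control, mode="legend",
            legend_suppress_alpha=1e-9,
        )
        assert single["a"] == "suppress"
        assert legend["a"] == "no_change"


class TestTsRescue:
    def outcome(self, strain, treated, control=80.0, n=60):
        return TsOutcome(strain, treated, control, n)

    def test_deep_reduction_rescues(self):
        rec = record("a", ts_outcomes={
            "unc-15": self.outcome("unc-15", 30.0),
            "unc-45": self.outcome("unc-45", 60.0),  # reduction 0.25: no
            "unc-54": self.outcome("unc-54", 75.0),
            "unc-52": self.outcome("unc-52", 20.0),
        })
        core, tallies = stage_ts_rescue([rec], {"a"})
        assert tallies["a"] == (2, 4)
        assert core == {"a"}

    def test_no_rescue_keeps_gene_out_of_core(self):
        rec = record("a", ts_outcomes={
            s: self.outcome(s, 70.0) for s in ("unc-15", "unc-45", "unc-54", "unc-52")
        })
        core, tallies = stage_ts_rescue([rec], {"a"})
        assert core == set() and tallies["a"] == (0, 4)

    def test_large_reduction_without_significance_fails(self):
        # tiny sample: 50% reduction but only 4 animals -> not significant
        rec = record("a", ts_outcomes={"unc-15": self.outcome("unc-15", 40.0, n=4)})
        core, tallies = stage_ts_rescue([rec], {"a"})
        assert tallies["a"] == (0, 1)

    def test_zero_control_raises(self):
        rec = record("a", ts_outcomes={"unc-15": self.outcome("unc-15", 0.0, control=0.0)})
        with pytest.raises(UndefinedReductionError):
            stage_ts_rescue([rec], {"a"})

    def test_missing_ts_data_raises(self):
        with pytest.raises(IncompleteRecordError):
            stage_ts_rescue([record("a")], {"a"})


class TestTalliesAndEnrichment:
    def test_single_class_set(self):
        records = [record(f"g{i}", functional_class="signaling") for i in range(5)]
        counts, fractions = functional_class_tally(records, {"g0", "g1", "g2"})
        assert counts["signaling"] == 3
        assert fractions["signaling"] == 1.0
        assert sum(counts.values()) == 3

    def test_empty_set_all_zero(self):
        counts, fractions = functional_class_tally([record("a")], set())
        assert all(v == 0 for v in counts.values())
        assert all(v == 0.0 for v in fractions.values())

    def test_chisq_zero_when_observed_equals_expected(self):
        chi2, df, p = enrichment_chisq({"a": 50, "b": 50}, {"a": 0.5, "b": 0.5}, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_chisq_hand_computed_two_class(self):
        chi2, df, p = enrichment_chisq({"a": 30, "b": 70}, {"a": 0.5, "b": 0.5}, 100)
        assert chi2 == pytest.approx(16.0)
        assert df == 1

    def test_chisq_symmetric_under_label_permutation(self):
        obs = {"a": 12, "b": 30, "c": 58}
        frac = {"a": 0.2, "b": 0.3, "c": 0.5}
        chi2a, _, pa = enrichment_chisq(obs, frac, 100)
        perm_obs = {"c": 58, "a": 12, "b": 30}
        chi2b, _, pb = enrichment_chisq(perm_obs, frac, 100)
        assert chi2a == pytest.approx(chi2b) and pa == pytest.approx(pb)

    def test_sparse_class_requires_pooling(self):
        with pytest.raises(PoolingRequiredError):
            enrichment_chisq({"a": 1, "b": 99}, {"a": 0.001, "b": 0.999}, 100)


class TestStatsHelpers:
    def test_pooled_t_matches_closed_form_reference(self):
        """Agreement with the textbook pooled-variance formula on random
        two-sample problems, to 6 significant figures of p."""
        from scipy import stats as sps

        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n1, n2 = rng.integers(3, 40, size=2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n1)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
            res = student_t_test(a, b)
            sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
            t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_ref = 2 * sps.t.sf(abs(t_ref), n1 + n2 - 2)
            assert res.statistic == pytest.approx(t_ref, rel=1e-9)
            assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_two_proportion_z_hand_example(self):
        # 30/60 vs 48/60: pooled 0.65, z = (0.5-0.8)/sqrt(0.65*0.35*2/60)
        res = two_proportion_z_test(30, 60, 48, 60)
        expected = (0.5 - 0.8) / np.sqrt(0.65 * 0.35 * (2 / 60))
        assert res.statistic == pytest.approx(expected)
        assert 0 < res.p_value < 0.01

    def test_degenerate_proportions(self):
        assert two_proportion_z_test(0, 10, 0, 10).p_value == 1.0

    @pytest.mark.parametrize(
        "x,expected",
        [(41.818, 42), (36.36, 36), (21.8, 22), (0.5, 1), (-0.5, -1), (2.5, 3)],
    )
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected
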