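"""Bland-Altman agreement, accuracy classification and equation ranking."""

import numpy as np
import pandas as pd
import pytest

import bmrkit as bk
from bmrkit.agreement import (
    accuracy_breakdown,
    accuracy_classify,
    agreement_stats,
    classify_predictions,
    evaluate_equations,
)
from bmrkit.equations import get_equation


class TestAgreementStats:
    def test_published_loa_arithmetic(self, rng):
        """Differences with mean 56 and SD 407 give limits -758 / 870 kJ/d."""
        n = 2000
        base = rng.normal(size=n)
        diff = 56 + 407 * (base - base.mean()) / base.std(ddof=1)
        measured = rng.normal(5600, 1000, n)
        rep = agreement_stats(measured, measured + diff, name="x")
        assert rep.bias == pytest.approx(56, abs=1e-9)
        assert rep.sd_diff == pytest.approx(407, abs=1e-9)
        assert rep.loa_low == pytest.approx(56 - 2 * 407)
        assert rep.loa_high == pytest.approx(870)

    def test_identity_prediction(self):
        m = np.array([5000.0, 6000.0, 7000.0])
        rep = agreement_stats(m, m, name="id")
        assert rep.bias == 0 and rep.sd_diff == 0
        assert (rep.loa_low, rep.loa_high) == (0, 0)
        assert rep.r2 == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        m = np.array([100.0, 200.0, 300.0])
        p = m + np.array([-1.0, 0.0, 1.0])
        rep = agreement_stats(m, p, name="x")
        assert rep.bias == pytest.approx(0.0)
        assert rep.sd_diff == pytest.approx(1.0)
        assert rep.loa_low == pytest.approx(-2.0)
        assert rep.loa_high == pytest.approx(2.0)

    def test_mean_pred_equals_mean_measured_plus_bias(self, default_cohort):
        m = default_cohort["bmr_measured"].to_numpy()
        p = get_equation("Singapore").predict(default_cohort)
        rep = agreement_stats(m, p, name="Singapore")
        assert rep.mean_pred == pytest.approx(m.mean() + rep.bias, rel=1e-12)

    def test_positive_bias_means_overestimation(self):
        m = np.full(5, 6000.0)
        p = m * 1.05 + np.arange(5)  # predictions above measurement
        rep = agreement_stats(m, p, name="x")
        assert rep.bias > 0

    def test_loa_multiplier_configurable(self, rng):
        m = rng.normal(6000, 500, 50)
        p = m + rng.normal(0, 300, 50)
        r196 = agreement_stats(m, p, loa_k=1.96)
        assert r196.loa_high == pytest.approx(r196.bias + 1.96 * r196.sd_diff)

    def test_two_sd_limits_cover_the_normal_share(self):
        """At n=10,000 Normal differences, bias ± 2 SD covers 95.45% ± 2pp."""
        rng = np.random.default_rng(5)
        m = rng.normal(6000, 800, 10_000)
        p = m + rng.normal(100, 400, 10_000)
        rep = agreement_stats(m, p, name="x")
        diff = p - m
        inside = np.mean((diff >= rep.loa_low) & (diff <= rep.loa_high))
        assert inside * 100 == pytest.approx(95.45, abs=2.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            agreement_stats([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            agreement_stats([1, 2], [1, 2])

    def test_directional_bias_slope_detected(self, rng):
        m = rng.normal(6000, 800, 400)
        p = m + 0.3 * (m - 6000) + rng.normal(0, 100, 400)
        rep = agreement_stats(m, p, name="x")
        assert rep.ba_slope > 0.1
        assert rep.ba_slope_p < 0.001


class TestAccuracy:
    @pytest.mark.parametrize(
        "measured,predicted,expected",
        [
            (6000, 6600, "accurate"),  # exact +10% boundary is accurate
            (6000, 6601, "over"),
            (6000, 5400, "accurate"),
            (6000, 5399, "under"),
            (6000, 6000, "accurate"),
        ],
    )
    def test_boundary_classification(self, measured, predicted, expected):
        assert accuracy_classify(measured, predicted) == expected

    def test_nonpositive_measured_errors(self):
        with pytest.raises(ValueError):
            accuracy_classify(0, 5000)

    def test_partition_is_exhaustive_and_sums_to_one(self, rng):
        m = rng.uniform(4000, 9000, 500)
        p = m * rng.uniform(0.7, 1.3, 500)
        labels = classify_predictions(m, p)
        counts = {k: np.sum(labels == k) for k in ("under", "accurate", "over")}
        assert sum(counts.values()) == 500
        scalar = [accuracy_classify(mi, pi) for mi, pi in zip(m, p)]
        assert list(labels) == scalar


class TestBreakdown:
    def test_perfect_prediction_is_all_accurate(self, default_cohort):
        df = default_cohort.copy()
        sg = get_equation("Singapore")
        df["bmr_measured"] = sg.predict(df)
        br = accuracy_breakdown(df, sg)
        for stratum in ("all", "le_cut", "gt_cut"):
            s = br.strata[stratum]
            assert (s["pct_under"], s["pct_accurate"], s["pct_over"]) == (0, 100, 0)

    def test_single_overestimated_subject(self):
        df = pd.DataFrame([
            {"id": "a", "sex": "M", "age": 30, "weight": 70.0, "height": 170.0,
             "bmr_measured": (52.6 * 70 + 2788) / 1.2},
        ])
        br = accuracy_breakdown(df, get_equation("Singapore"))
        assert br.strata["all"]["pct_over"] == 100.0
        assert br.strata["all"]["pct_accurate"] == 0.0

    def test_empty_stratum_reported_absent(self):
        df = pd.DataFrame([
            {"id": "a", "sex": "F", "age": 30, "weight": 50.0, "height": 170.0,
             "bmr_measured": 4600.0},  # BMI 17.3, below the cut
        ])
        br = accuracy_breakdown(df, get_equation("Singapore"))
        assert br.strata["gt_cut"] is None
        assert br.strata["le_cut"]["n"] == 1

    def test_percentages_sum_to_100_per_stratum(self, default_cohort):
        br = accuracy_breakdown(default_cohort, get_equation("Owen"))
        for s in br.strata.values():
            if s is not None:
                total = s["pct_under"] + s["pct_accurate"] + s["pct_over"]
                assert total == pytest.approx(100.0, abs=1e-9)


class TestEvaluate:
    def test_singapore_ranks_first_on_generator_cohort(self, default_cohort, registry):
        ev = evaluate_equations(default_cohort, registry)
        assert ev.reports[0].equation_name == "Singapore"
        accs = [b.pct_accurate for b in ev.breakdowns]
        assert accs == sorted(accs, reverse=True)

    def test_single_equation_registry(self, default_cohort):
        ev = evaluate_equations(default_cohort, [get_equation("Owen")])
        assert len(ev.reports) == 1

    def test_rerun_is_bit_identical(self, default_cohort, registry):
        a = evaluate_equations(default_cohort, registry).to_frame()
        b = evaluate_equations(default_cohort, registry).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_uncovered_ages_skip_policy(self, registry):
        df = pd.DataFrame([
            {"id": f"s{i}", "sex": "M", "age": 75.0, "weight": 70.0,
             "height": 170.0, "bmr_measured": 6500.0}
            for i in range(5)
        ])
        with pytest.raises(bk.BandDispatchError):
            evaluate_equations(df, registry, on_dispatch_error="fail")
        ev = evaluate_equations(df, registry, on_dispatch_error="skip")
        assert "Henry" in ev.skipped
        assert all(r.equation_name != "Henry" for r in ev.reports)

    def test_empty_inputs_error(self, registry, default_cohort):
        with pytest.raises(ValueError):
            evaluate_equations(default_cohort.iloc[:0], registry)
        with pytest.raises(ValueError):
            evaluate_equations(default_cohort, [])
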