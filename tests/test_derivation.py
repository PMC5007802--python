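"""OLS fitting, forward stepwise selection and equation rendering."""

import numpy as np
import pandas as pd
import pytest

import bmrkit as bk
from bmrkit.derivation import (
    RankDeficiencyError,
    StepwiseBmr,
    fit_ols,
    render_equation,
    stepwise_derive,
)
from conftest import normal_equations_ols


def noiseless_cohort(n=10, seed=3):
    rng = np.random.default_rng(seed)
    w = rng.uniform(45, 110, n)
    sex = np.where(np.arange(n) % 2 == 0, "M", "F")
    g = (sex == "M").astype(float)
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "sex": sex,
        "age": rng.uniform(21, 60, n),
        "weight": w,
        "height": rng.uniform(150, 185, n),
        "bmr_measured": 52.6 * w + 828 * g + 1960,
    })


class TestFitOls:
    def test_noiseless_plane_recovered_to_machine_precision(self):
        df = noiseless_cohort()
        fit = StepwiseBmr.from_cohort(df, ["weight", "gender"]).fit_full()
        assert fit.coefficient("weight") == pytest.approx(52.6, rel=1e-10)
        assert fit.coefficient("gender") == pytest.approx(828, rel=1e-10)
        assert fit.intercept == pytest.approx(1960, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rd == pytest.approx(0.0, abs=1e-6)

    def test_three_point_hand_solved_regression(self):
        # (0,0),(1,1),(2,2.1): slope 1.05, intercept -1/60 by normal equations
        fit = fit_ols([0.0, 1.0, 2.1], np.array([[0.0], [1.0], [2.0]]))
        assert fit.params["x0"] == pytest.approx(1.05)
        assert fit.intercept == pytest.approx(-1 / 60)

    @pytest.mark.parametrize("ncov", [1, 2, 3, 5])
    def test_matches_normal_equations_oracle(self, ncov, rng):
        for _ in range(25):
            n = int(rng.integers(ncov + 3, 40))
            X = rng.normal(size=(n, ncov))
            y = rng.normal(size=n) + X @ rng.normal(size=ncov)
            fit = fit_ols(y, X)
            beta, r2, rd = normal_equations_ols(y, X)
            got = np.concatenate([[fit.intercept],
                                  [fit.params[f"x{i}"] for i in range(ncov)]])
            np.testing.assert_allclose(got, beta, rtol=1e-8)
            assert fit.r2 == pytest.approx(r2, rel=1e-8)
            assert fit.rd == pytest.approx(rd, rel=1e-8)

    def test_residuals_sum_to_zero(self, default_cohort):
        fit = StepwiseBmr.from_cohort(default_cohort, ["weight", "gender"]).fit_full()
        y = default_cohort["bmr_measured"].to_numpy()
        assert abs(fit.resid.mean()) < 1e-6 * y.mean()

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_ols(rng.normal(size=20), X)


class TestStepwise:
    def test_selects_weight_then_gender_on_generator_data(self, default_cohort):
        fit = stepwise_derive(default_cohort)
        assert fit.included[:2] == ["weight", "gender"]
        trace_names = [s.covariate for s in fit.step_trace]
        assert trace_names[:2] == ["weight", "gender"]
        # RD decreases weakly along the trace
        rds = [s.rd for s in fit.step_trace]
        assert all(a >= b for a, b in zip(rds, rds[1:]))

    def test_height_or_age_rarely_enter(self):
        extra = 0
        n_rep = 60
        for child in np.random.SeedSequence(99).spawn(n_rep):
            cohort = bk.generate_cohort(seed=np.random.default_rng(child))
            fit = stepwise_derive(cohort)
            extra += set(fit.included) != {"weight", "gender"}
        assert extra / n_rep <= 0.15

    def test_step_trace_rds_near_published_path(self):
        """Across replicates the RD path averages ~656 then ~534 kJ/d."""
        rd1, rd2 = [], []
        for child in np.random.SeedSequence(123).spawn(50):
            fit = stepwise_derive(bk.generate_cohort(seed=np.random.default_rng(child)))
            rd1.append(fit.step_trace[0].rd)
            rd2.append(fit.step_trace[1].rd)
        assert np.mean(rd1) == pytest.approx(656, abs=12)
        assert np.mean(rd2) == pytest.approx(534, abs=10)

    def test_empty_candidates_gives_intercept_only_fit(self, default_cohort):
        fit = stepwise_derive(default_cohort, candidates=[])
        y = default_cohort["bmr_measured"].to_numpy()
        assert fit.included == []
        assert fit.rd == pytest.approx(y.std(ddof=1), rel=1e-10)
        assert fit.intercept == pytest.approx(y.mean(), rel=1e-10)

    def test_single_sex_cohort_with_gender_candidate_errors(self):
        df = noiseless_cohort(12)
        df["sex"] = "M"
        df["bmr_measured"] = 52.6 * df["weight"] + 828 + 1960
        with pytest.raises(RankDeficiencyError):
            stepwise_derive(df, candidates=["weight", "gender"])

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            stepwise_derive(pd.DataFrame(columns=["id", "sex", "age", "weight",
                                                  "height", "bmr_measured"]))

    def test_missing_bmr_errors(self, default_cohort):
        df = default_cohort.copy()
        df.loc[df.index[0], "bmr_measured"] = np.nan
        with pytest.raises(ValueError, match="without measured BMR"):
            stepwise_derive(df)

    def test_bidirectional_matches_forward_on_generator_data(self, default_cohort):
        fwd = stepwise_derive(default_cohort, method="forward")
        both = stepwise_derive(default_cohort, method="bidirectional")
        assert set(fwd.included) == set(both.included)


class TestParameterRecovery:
    def test_mean_coefficients_near_truth_over_replicates(self):
        """Monte-Carlo recovery of the generating coefficients (52.6, 828)."""
        wc, gc = [], []
        for child in np.random.SeedSequence(2024).spawn(200):
            cohort = bk.generate_cohort(seed=np.random.default_rng(child))
            fit = StepwiseBmr.from_cohort(cohort, ["weight", "gender"]).fit_full()
            wc.append(fit.coefficient("weight"))
            gc.append(fit.coefficient("gender"))
        assert np.mean(wc) == pytest.approx(52.6, abs=0.5)
        assert np.mean(gc) == pytest.approx(828, abs=15)


class TestRenderEquation:
    def test_gender_folds_into_per_sex_intercepts(self):
        df = noiseless_cohort(20)
        eq = stepwise_derive(df, candidates=["weight", "gender"]).to_equation("new")
        assert eq.predict_one("M", 30, 0.001, 170) == pytest.approx(2788, abs=0.1)
        assert eq.predict_one("F", 30, 0.001, 170) == pytest.approx(1960, abs=0.1)
        assert eq.predict_one("M", 30, 79.2, 171.7) == pytest.approx(
            52.6 * 79.2 + 2788, rel=1e-9)

    def test_no_gender_term_gives_identical_rows(self):
        df = noiseless_cohort(20)
        fit = stepwise_derive(df, candidates=["weight"])
        eq = render_equation(fit)
        assert eq.predict_one("M", 30, 70, 170) == eq.predict_one("F", 30, 70, 170)

    def test_weight_and_height_appear_in_both_rows(self):
        df = noiseless_cohort(20)
        fit = StepwiseBmr.from_cohort(df, ["weight", "height"]).fit_full()
        eq = render_equation(fit)
        for b in eq.bands:
            assert b.w == pytest.approx(fit.coefficient("weight"))
            assert b.h == pytest.approx(fit.coefficient("height"))
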