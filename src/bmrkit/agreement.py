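"""Agreement and accuracy evaluation of BMR prediction equations.

For each equation on a measured cohort this module reports, Bland-Altman
style: the bias (mean of predicted − measured, so positive means
overestimation), the SD of the differences, limits of agreement defined as
bias ± 2 SD, a paired t-test, the R^2 between measured and predicted, and
the regression of differences on pairwise averages (directional bias).
Accuracy classifies each prediction as within ±10% of the measured value
(accurate), above +10% (over) or below −10% (under), optionally stratified
by BMI at the Asian overweight cut-off of 23 kg/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equations import BandDispatchError, PredictionEquation
from .subjects import as_frame, bmi_two_way, compute_bmi

__all__ = [
    "AgreementReport",
    "AccuracyBreakdown",
    "EquationEvaluation",
    "agreement_stats",
    "accuracy_classify",
    "classify_predictions",
    "accuracy_breakdown",
    "evaluate_equations",
    "bland_altman_plot",
]

#: Limits-of-agreement multiplier; the study defines the limits as ±2 SD.
DEFAULT_LOA_K = 2.0
#: Accuracy band: within ±10% of the measured value.
DEFAULT_ACCURACY_TOL = 0.10


@dataclass
class AgreementReport:
    """Bland-Altman style agreement of one equation with measured BMR."""

    equation_name: str
    n: int
    mean_pred: float  # kJ/d
    sd_pred: float
    bias: float  # kJ/d, predicted − measured
    sd_diff: float
    p_paired_t: float
    r2: float
    loa_low: float
    loa_high: float
    ba_slope: float  # slope of (pred − meas) on (pred + meas)/2
    ba_r2: float
    ba_slope_p: float
    _avg: np.ndarray = field(default=None, repr=False)
    _diff: np.ndarray = field(default=None, repr=False)

    def summary(self) -> str:
        return (
            f"{self.equation_name}: n={self.n}, predicted "
            f"{self.mean_pred:.0f} ± {self.sd_pred:.0f} kJ/d, bias "
            f"{self.bias:.0f} ± {self.sd_diff:.0f} kJ/d (p={self.p_paired_t:.3g}), "
            f"R^2={self.r2:.2f}, LoA [{self.loa_low:.0f}, {self.loa_high:.0f}] kJ/d, "
            f"slope {self.ba_slope:.3f} (p={self.ba_slope_p:.3g})"
        )

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if not k.startswith("_")
        }


@dataclass
class AccuracyBreakdown:
    """Under/accurate/over percentages, overall and by BMI stratum.

    `strata` maps stratum label ("all", "le_cut", "gt_cut") to a dict with
    keys pct_under/pct_accurate/pct_over (full precision, summing to 100)
    and n; an empty stratum maps to None.
    """

    equation_name: str
    bmi_cut: float
    strata: dict[str, Optional[dict]]

    @property
    def pct_accurate(self) -> float:
        return self.strata["all"]["pct_accurate"]

    @property
    def pct_under(self) -> float:
        return self.strata["all"]["pct_under"]

    @property
    def pct_over(self) -> float:
        return self.strata["all"]["pct_over"]

    def to_dict(self) -> dict:
        return {
            "equation_name": self.equation_name,
            "bmi_cut": self.bmi_cut,
            "strata": self.strata,
        }


def agreement_stats(measured, predicted, name: str = "",
                    loa_k: float = DEFAULT_LOA_K) -> AgreementReport:
    """Full agreement battery for one equation.

    Differences are predicted − measured; sd_diff uses the sample SD
    (ddof=1); the limits of agreement are bias ± loa_k·sd_diff.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: measured {m.shape} vs predicted {p.shape}")
    n = len(m)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    diff = p - m
    avg = (p + m) / 2.0
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if np.allclose(diff, diff[0]):
        p_t = 1.0 if abs(bias) < 1e-12 else 0.0
    else:
        p_t = float(stats.ttest_rel(p, m).pvalue)
    if m.std() == 0 or p.std() == 0:
        r2 = 1.0 if np.allclose(p, m) else 0.0
    else:
        r2 = float(stats.pearsonr(m, p)[0] ** 2)
    if avg.std() == 0 or sd_diff == 0:
        slope, ba_r2, slope_p = 0.0, 0.0, 1.0
    else:
        reg = stats.linregress(avg, diff)
        slope, ba_r2, slope_p = float(reg.slope), float(reg.rvalue**2), float(reg.pvalue)
    return AgreementReport(
        equation_name=name,
        n=n,
        mean_pred=float(p.mean()),
        sd_pred=float(p.std(ddof=1)),
        bias=bias,
        sd_diff=sd_diff,
        p_paired_t=p_t,
        r2=r2,
        loa_low=bias - loa_k * sd_diff,
        loa_high=bias + loa_k * sd_diff,
        ba_slope=slope,
        ba_r2=ba_r2,
        ba_slope_p=slope_p,
        _avg=avg,
        _diff=diff,
    )


def accuracy_classify(measured: float, predicted: float,
                      tol: float = DEFAULT_ACCURACY_TOL) -> str:
    """'accurate' iff |predicted − measured| ≤ tol·measured (boundary in)."""
    if not measured > 0:
        raise ValueError(f"measured BMR must be positive, got {measured}")
    if predicted > (1 + tol) * measured:
        return "over"
    if predicted < (1 - tol) * measured:
        return "under"
    return "accurate"


def classify_predictions(measured, predicted,
                         tol: float = DEFAULT_ACCURACY_TOL) -> np.ndarray:
    """Vectorised accuracy classification -> array of 'under'/'accurate'/'over'."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if np.any(m <= 0):
        raise ValueError("measured BMR must be positive")
    out = np.full(m.shape, "accurate", dtype=object)
    out[p > (1 + tol) * m] = "over"
    out[p < (1 - tol) * m] = "under"
    return out


def _stratum_pcts(labels: np.ndarray) -> Optional[dict]:
    n = len(labels)
    if n == 0:
        return None
    return {
        "n": int(n),
        "pct_under": 100.0 * float(np.mean(labels == "under")),
        "pct_accurate": 100.0 * float(np.mean(labels == "accurate")),
        "pct_over": 100.0 * float(np.mean(labels == "over")),
    }


def accuracy_breakdown(cohort, eq: PredictionEquation, bmi_cut: float = 23.0,
                       tol: float = DEFAULT_ACCURACY_TOL,
                       predicted: Optional[np.ndarray] = None) -> AccuracyBreakdown:
    """Accuracy percentages overall and split at the BMI cut (≤cut vs >cut)."""
    df = as_frame(cohort)
    if df["bmr_measured"].isna().any():
        raise ValueError("accuracy breakdown requires measured BMR for all subjects")
    measured = df["bmr_measured"].to_numpy(dtype=float)
    if predicted is None:
        predicted = eq.predict(df)
    labels = classify_predictions(measured, predicted, tol=tol)
    above = bmi_two_way(compute_bmi(df["weight"], df["height"]), cut=bmi_cut)
    return AccuracyBreakdown(
        equation_name=eq.name,
        bmi_cut=bmi_cut,
        strata={
            "all": _stratum_pcts(labels),
            "le_cut": _stratum_pcts(labels[~above]),
            "gt_cut": _stratum_pcts(labels[above]),
        },
    )


@dataclass
class EquationEvaluation:
    """Ranked evaluation of a registry of equations on one cohort."""

    reports: list[AgreementReport]
    breakdowns: list[AccuracyBreakdown]
    skipped: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, br in zip(self.reports, self.breakdowns):
            rows.append(
                {
                    "equation": rep.equation_name,
                    "n": rep.n,
                    "mean_pred": rep.mean_pred,
                    "sd_pred": rep.sd_pred,
                    "bias": rep.bias,
                    "sd_diff": rep.sd_diff,
                    "p_paired_t": rep.p_paired_t,
                    "r2": rep.r2,
                    "loa_low": rep.loa_low,
                    "loa_high": rep.loa_high,
                    "ba_slope": rep.ba_slope,
                    "ba_r2": rep.ba_r2,
                    "ba_slope_p": rep.ba_slope_p,
                    "pct_under": br.pct_under,
                    "pct_accurate": br.pct_accurate,
                    "pct_over": br.pct_over,
                    "pct_under_le": _get(br, "le_cut", "pct_under"),
                    "pct_accurate_le": _get(br, "le_cut", "pct_accurate"),
                    "pct_over_le": _get(br, "le_cut", "pct_over"),
                    "pct_under_gt": _get(br, "gt_cut", "pct_under"),
                    "pct_accurate_gt": _get(br, "gt_cut", "pct_accurate"),
                    "pct_over_gt": _get(br, "gt_cut", "pct_over"),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Equation evaluation (ranked by overall accuracy):"]
        for rep, br in zip(self.reports, self.breakdowns):
            lines.append(f"  {rep.summary()}")
            lines.append(
                f"    accuracy: {br.pct_under:.0f}% under / "
                f"{br.pct_accurate:.0f}% accurate / {br.pct_over:.0f}% over"
            )
        for name, reason in self.skipped.items():
            lines.append(f"  [skipped] {name}: {reason}")
        return "\n".join(lines)


def _get(br: AccuracyBreakdown, stratum: str, key: str):
    s = br.strata.get(stratum)
    return np.nan if s is None else s[key]


def evaluate_equations(cohort, eqs: Sequence[PredictionEquation],
                       bmi_cut: float = 23.0, loa_k: float = DEFAULT_LOA_K,
                       tol: float = DEFAULT_ACCURACY_TOL,
                       on_dispatch_error: str = "fail") -> EquationEvaluation:
    """Evaluate every equation, ranked by accuracy (ties by |bias|).

    `on_dispatch_error` controls what happens when an equation cannot cover
    a subject's age: "fail" raises, "skip" evaluates the equation on the
    covered subjects only (dropping it entirely if none are covered, with a
    note in `skipped`).
    """
    df = as_frame(cohort)
    if df.empty or not eqs:
        raise ValueError("need a non-empty cohort and at least one equation")
    if on_dispatch_error not in ("fail", "skip"):
        raise ValueError("on_dispatch_error must be 'fail' or 'skip'")
    measured = df["bmr_measured"].to_numpy(dtype=float)
    if np.isnan(measured).any():
        raise ValueError("evaluation requires measured BMR for all subjects")
    results = []
    skipped: dict[str, str] = {}
    for eq in eqs:
        sub = df
        m = measured
        try:
            pred = eq.predict(sub)
        except BandDispatchError as err:
            if on_dispatch_error == "fail":
                raise
            covered = np.array([
                _covers(eq, s, a) for s, a in zip(df["sex"], df["age"])
            ])
            if not covered.any():
                skipped[eq.name] = f"no subjects within age bands ({err})"
                continue
            sub = df.loc[covered]
            m = measured[covered]
            pred = eq.predict(sub)
        rep = agreement_stats(m, pred, name=eq.name, loa_k=loa_k)
        br = accuracy_breakdown(sub, eq, bmi_cut=bmi_cut, tol=tol, predicted=pred)
        results.append((rep, br))
    results.sort(key=lambda rb: (-rb[1].pct_accurate, abs(rb[0].bias)))
    return EquationEvaluation(
        reports=[r for r, _ in results],
        breakdowns=[b for _, b in results],
        skipped=skipped,
    )


def _covers(eq: PredictionEquation, sex, age) -> bool:
    try:
        eq.predict_one(sex, float(age), 70.0, 170.0)
        return True
    except BandDispatchError:
        return False


def bland_altman_plot(report: AgreementReport, ax=None):
    """Difference-vs-average plot with bias, LoA and the trend line."""
    import matplotlib.pyplot as plt

    if report._avg is None or report._diff is None:
        raise ValueError("report carries no per-subject data to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report._avg, report._diff, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(report.bias, linestyle=":", color="k", label=f"bias {report.bias:.0f}")
    ax.axhline(report.loa_low, color="k", lw=1)
    ax.axhline(report.loa_high, color="k", lw=1)
    xs = np.linspace(report._avg.min(), report._avg.max(), 2)
    intercept = report.bias - report.ba_slope * report._avg.mean()
    ax.plot(xs, intercept + report.ba_slope * xs, "r-", lw=1,
            label=f"slope {report.ba_slope:.3f} (p={report.ba_slope_p:.2g})")
    ax.set_xlabel("average of measured and predicted BMR (kJ/d)")
    ax.set_ylabel("predicted − measured BMR (kJ/d)")
    ax.set_title(report.equation_name)
    ax.legend(fontsize=8)
    return ax
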