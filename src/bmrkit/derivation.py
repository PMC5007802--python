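"""Derivation of a BMR prediction equation by forward stepwise OLS.

The model regresses measured BMR (kJ/d) on a candidate set of
anthropometric covariates — weight (kg), height (cm), age (years) and the
gender dummy (men = 1, women = 0) — selecting covariates forward: at each
step the candidate giving the largest drop in residual standard deviation
(RD, kJ/d) enters if its partial test is significant at the entry level
(default p < 0.05); selection stops when no candidate qualifies. Goodness
of fit is reported as R^2 and RD = sqrt(SSE / (n - k - 1)).

Organised statsmodels-style: :class:`StepwiseBmr` is the model,
``fit()`` returns :class:`StepwiseBmrResults` with coefficients, standard
errors, the step trace and a ``summary()`` table; the fitted equation can
be rendered as a per-sex :class:`~bmrkit.equations.PredictionEquation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .equations import ADULT_AGE_MAX, ADULT_AGE_MIN, Band, PredictionEquation
from .subjects import Sex, as_frame

__all__ = [
    "StepwiseBmr",
    "StepwiseBmrResults",
    "StepRecord",
    "RankDeficiencyError",
    "fit_ols",
    "stepwise_derive",
    "render_equation",
]

DEFAULT_CANDIDATES = ("weight", "height", "age", "gender")


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class StepRecord:
    covariate: str
    rd: float  # kJ/d after this covariate entered
    p_enter: float  # partial-test p-value at entry


@dataclass
class StepwiseBmrResults:
    """Fitted equation: coefficients, fit statistics and the step trace."""

    included: list[str]
    params: pd.Series  # intercept under 'const', kJ/d per covariate unit
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    rd: float  # kJ/d
    nobs: int
    step_trace: list[StepRecord] = field(default_factory=list)
    resid: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def coefficient(self, name: str) -> float:
        return float(self.params.get(name, 0.0))

    def to_equation(self, name: str = "derived") -> PredictionEquation:
        return render_equation(self, name=name)

    def summary(self) -> str:
        lines = [
            f"Stepwise BMR equation (n = {self.nobs})",
            f"  R^2 = {self.r2:.3f}   RD = {self.rd:.1f} kJ/d",
            f"  {'term':<10}{'coef':>12}{'std err':>12}{'P>|t|':>10}",
        ]
        for term in self.params.index:
            lines.append(
                f"  {term:<10}{self.params[term]:>12.4g}"
                f"{self.bse[term]:>12.4g}{self.pvalues[term]:>10.3g}"
            )
        if self.step_trace:
            lines.append("  selection trace:")
            for s in self.step_trace:
                lines.append(
                    f"    + {s.covariate:<8} RD -> {s.rd:7.1f} kJ/d  (p = {s.p_enter:.3g})"
                )
        return "\n".join(lines)


def _check_rank(X: pd.DataFrame) -> None:
    A = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify dependent columns via pivoted QR: pivots beyond the rank
        from scipy.linalg import qr

        _, _, piv = qr(A, mode="economic", pivoting=True)
        collinear = [X.columns[i] for i in sorted(piv[rank:])]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {A.shape[1]} columns; "
            f"collinear columns: {collinear}"
        )


def _ols(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc)
    return sm.OLS(y, Xc).fit()


def _rd(res) -> float:
    # statsmodels mse_resid uses df_resid = n - k - 1, exactly the RD definition
    return float(np.sqrt(res.mse_resid))


class StepwiseBmr:
    """Stepwise OLS model of measured BMR on anthropometric candidates.

    Parameters
    ----------
    endog : array-like
        Measured BMR, kJ/d.
    exog : DataFrame
        Candidate covariates, one column per candidate.
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = pd.DataFrame(exog).astype(float).reset_index(drop=True)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if len(self.endog) < len(self.exog.columns) + 2:
            raise ValueError("need n > number of candidates + 1 observations")
        if np.isnan(self.endog).any():
            raise ValueError("endog contains missing values")

    @classmethod
    def from_cohort(cls, cohort, candidates: Sequence[str] = DEFAULT_CANDIDATES
                    ) -> "StepwiseBmr":
        """Build the model from a cohort table with measured BMR.

        The gender candidate is coded men = 1, women = 0.
        """
        df = as_frame(cohort)
        if df.empty:
            raise ValueError("empty cohort")
        if df["bmr_measured"].isna().any():
            missing = df.loc[df["bmr_measured"].isna(), "id"].tolist()
            raise ValueError(f"subjects without measured BMR: {missing}")
        X = pd.DataFrame(index=df.index)
        for c in candidates:
            if c == "gender":
                X[c] = (df["sex"] == Sex.MALE.value).astype(float)
            elif c in ("weight", "height", "age"):
                X[c] = df[c].astype(float)
            else:
                raise ValueError(f"unknown candidate covariate {c!r}")
        return cls(df["bmr_measured"].to_numpy(dtype=float), X)

    def fit(self, entry_p: float = 0.05, method: str = "forward",
            remove_p: float = 0.10) -> StepwiseBmrResults:
        """Run the selection and fit the final equation.

        method="forward" adds covariates only; method="bidirectional" also
        drops an included covariate whose partial p rises to `remove_p` or
        beyond after each addition.
        """
        if method not in ("forward", "bidirectional"):
            raise ValueError(f"unknown method {method!r}")
        included: list[str] = []
        trace: list[StepRecord] = []
        remaining = list(self.exog.columns)
        while remaining:
            best = None  # (rd, name, p_enter)
            for cand in sorted(remaining):  # alphabetical tie-break via stable min
                res = _ols(self.endog, self.exog[included + [cand]])
                cand_rd = _rd(res)
                if best is None or cand_rd < best[0] - 1e-12:
                    best = (cand_rd, cand, float(res.pvalues[cand]))
            rd_new, name, p_enter = best
            if p_enter >= entry_p:
                break
            included.append(name)
            remaining.remove(name)
            trace.append(StepRecord(name, rd_new, p_enter))
            if method == "bidirectional" and len(included) > 1:
                res = _ols(self.endog, self.exog[included])
                worst = max(included, key=lambda c: float(res.pvalues[c]))
                if float(res.pvalues[worst]) >= remove_p and worst != name:
                    included.remove(worst)
                    remaining.append(worst)
        return self._finalize(included, trace)

    def fit_full(self) -> StepwiseBmrResults:
        """Plain OLS on every candidate, no selection."""
        return self._finalize(list(self.exog.columns), trace=[])

    def _finalize(self, included: list[str], trace: list[StepRecord]
                  ) -> StepwiseBmrResults:
        res = _ols(self.endog, self.exog[included])
        return StepwiseBmrResults(
            included=list(included),
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            r2=float(res.rsquared) if included else 0.0,
            rd=_rd(res),
            nobs=int(res.nobs),
            step_trace=trace,
            resid=np.asarray(res.resid),
        )


def fit_ols(y, X: Union[pd.DataFrame, np.ndarray]) -> StepwiseBmrResults:
    """Ordinary least squares with intercept on all given covariates.

    Thin functional wrapper over :meth:`StepwiseBmr.fit_full`; columns of a
    bare array are named x0, x1, ...
    """
    if not isinstance(X, pd.DataFrame):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(y)) != 1:
            X = X.T
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    return StepwiseBmr(y, X).fit_full()


def stepwise_derive(cohort, candidates: Sequence[str] = DEFAULT_CANDIDATES,
                    entry_p: float = 0.05, method: str = "forward",
                    remove_p: float = 0.10) -> StepwiseBmrResults:
    """Forward-stepwise equation derivation from a measured cohort."""
    if not candidates:
        df = as_frame(cohort)
        y = df["bmr_measured"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("cohort contains subjects without measured BMR")
        model = StepwiseBmr(y, pd.DataFrame({"_null": np.zeros(len(y))}))
        return model._finalize([], trace=[])
    model = StepwiseBmr.from_cohort(cohort, candidates)
    return model.fit(entry_p=entry_p, method=method, remove_p=remove_p)


def render_equation(fit: StepwiseBmrResults, name: str = "derived"
                    ) -> PredictionEquation:
    """Fold the gender dummy into per-sex intercepts.

    Produces a two-row adult equation: the men's intercept absorbs the
    gender coefficient (men = 1); weight/height/age coefficients are shared
    between sexes. Coefficients are kept at full precision.
    """
    g = fit.coefficient("gender")
    common = dict(w=fit.coefficient("weight"), h=fit.coefficient("height"),
                  a=fit.coefficient("age"))
    return PredictionEquation(
        name,
        (
            Band(Sex.MALE, ADULT_AGE_MIN, ADULT_AGE_MAX, fit.intercept + g, **common),
            Band(Sex.FEMALE, ADULT_AGE_MIN, ADULT_AGE_MAX, fit.intercept, **common),
        ),
    )
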