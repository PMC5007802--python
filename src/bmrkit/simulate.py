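"""Synthetic study cohorts and ventilated-hood traces.

The cohort generator emulates the study population used to derive and
validate the Singapore equation: fixed per-sex counts, truncated-Normal
weight/height/age with the published per-sex means and SDs, and a measured
BMR built from the equation's mean structure

    BMR (kJ/d) = 1960 + 52.6 * weight + 828 * gender + Normal(0, 534)

with gender = 1 for men. Two presets are provided: the cross-sectional
derivation cohort (121 men / 111 women) and the smaller cross-validation
cohort (26 men / 44 women). Covariates are sampled independently within
sex (an optional weight-height correlation is available but defaults to 0,
as the study reports no covariance structure).

The gas-trace generator inverts the Weir equation at a chosen respiratory
quotient so that the flat part of a 30-min, 5-s-sampled trace encodes a
target BMR, with an exponentially decaying habituation transient and
multiplicative Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .calorimetry import (
    GasExchangeSeries,
    KJ_PER_KCAL,
    MIN_PER_DAY,
    WEIR_VCO2_KCAL_PER_L,
    WEIR_VO2_KCAL_PER_L,
)
from .subjects import COHORT_COLUMNS, Sex

__all__ = [
    "SexMoments",
    "CohortSpec",
    "GasTraceSpec",
    "cross_sectional_spec",
    "cross_validation_spec",
    "generate_cohort",
    "generate_validation_cohort",
    "generate_gas_series",
]


@dataclass(frozen=True)
class SexMoments:
    """Per-sex sampling moments: count plus mean/SD of weight, height, age."""

    n: int
    weight_mean: float  # kg
    weight_sd: float
    height_mean: float  # cm
    height_sd: float
    age_mean: float  # years
    age_sd: float


Range = Optional[Tuple[float, float]]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one synthetic cohort reproducibly.

    A range of None leaves that covariate untruncated. By default only age
    (the adult study range) and height carry bounds; weight is plain Normal
    with the published per-sex SD, since truncating at a pooled observed
    range would clip the women's weight distribution asymmetrically and
    shrink the very variance the model statistics depend on.
    """

    men: SexMoments
    women: SexMoments
    weight_range: Range = None
    height_range: Range = None
    age_range: Range = None
    # true mean structure of measured BMR (kJ/d)
    coeff_intercept: float = 1960.0
    coeff_weight: float = 52.6
    coeff_gender: float = 828.0
    residual_sd: float = 534.0  # kJ/d
    wh_corr: float = 0.0  # weight-height correlation within sex
    id_prefix: str = "S"

    def __post_init__(self):
        for m in (self.men, self.women):
            for sd in (m.weight_sd, m.height_sd, m.age_sd):
                if not sd > 0:
                    raise ValueError("all SDs must be positive")
        if not self.residual_sd >= 0:
            raise ValueError("residual_sd must be non-negative")
        if not -1 < self.wh_corr < 1:
            raise ValueError("wh_corr must lie in (-1, 1)")
        for rng_, label in ((self.weight_range, "weight"),
                            (self.height_range, "height"),
                            (self.age_range, "age")):
            if rng_ is not None:
                lo, hi = rng_
                if not lo < hi:
                    raise ValueError(f"{label}_range must be increasing")

    @property
    def n_total(self) -> int:
        return self.men.n + self.women.n


def cross_sectional_spec(**overrides) -> CohortSpec:
    """Derivation-cohort preset: 121 men / 111 women, published moments."""
    spec = CohortSpec(
        men=SexMoments(121, 79.2, 14.9, 171.7, 5.9, 32.3, 9.9),
        women=SexMoments(111, 66.1, 16.1, 159.9, 6.2, 33.4, 11.2),
        height_range=(147.4, 189.3),
        age_range=(21.6, 66.8),
        id_prefix="CS",
    )
    return replace(spec, **overrides) if overrides else spec


def cross_validation_spec(**overrides) -> CohortSpec:
    """Validation-cohort preset: 26 men / 44 women, published moments."""
    spec = CohortSpec(
        men=SexMoments(26, 72.1, 13.3, 173.4, 6.3, 28.2, 6.3),
        women=SexMoments(44, 59.7, 15.6, 162.3, 5.3, 28.8, 10.2),
        height_range=(151.9, 185.5),
        age_range=(21.6, 66.8),
        id_prefix="CV",
    )
    return replace(spec, **overrides) if overrides else spec


PRESETS = {
    "cross_sectional": cross_sectional_spec,
    "cross_validation": cross_validation_spec,
}

_MAX_REJECTION_ROUNDS = 1000


def _check_feasible(mean: float, sd: float, rng_range: Range, label: str):
    if rng_range is None:
        return
    lo, hi = rng_range
    if hi < mean - 6 * sd or lo > mean + 6 * sd:
        raise ValueError(
            f"{label}: range ({lo}, {hi}) excludes mean ± 6 SD "
            f"({mean} ± {6 * sd:.1f}); truncation infeasible"
        )


def _in_range(x: np.ndarray, rng_range: Range) -> np.ndarray:
    if rng_range is None:
        return np.ones(len(x), dtype=bool)
    return (x >= rng_range[0]) & (x <= rng_range[1])


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      rng_range: Range, label: str) -> np.ndarray:
    """Normal(mean, sd) draws, rejection-sampled against the range if any."""
    _check_feasible(mean, sd, rng_range, label)
    if rng_range is None:
        return rng.normal(mean, sd, size=n)
    out = np.empty(0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.normal(mean, sd, size=max(2 * (n - len(out)), 16))
        out = np.concatenate([out, draw[_in_range(draw, rng_range)]])
        if len(out) >= n:
            return out[:n]
    raise ValueError(f"{label}: rejection sampling failed to fill {n} draws")


def _truncated_bivariate(rng: np.random.Generator, n: int,
                         mw: float, sw: float, mh: float, sh: float,
                         corr: float, wr: Range, hr: Range
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Correlated (weight, height) pairs rejected jointly against both ranges."""
    _check_feasible(mw, sw, wr, "weight")
    _check_feasible(mh, sh, hr, "height")
    cov = [[sw**2, corr * sw * sh], [corr * sw * sh, sh**2]]
    w = np.empty(0)
    h = np.empty(0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.multivariate_normal([mw, mh], cov, size=max(2 * (n - len(w)), 16))
        ok = _in_range(draw[:, 0], wr) & _in_range(draw[:, 1], hr)
        w = np.concatenate([w, draw[ok, 0]])
        h = np.concatenate([h, draw[ok, 1]])
        if len(w) >= n:
            return w[:n], h[:n]
    raise ValueError("joint rejection sampling failed")


def generate_cohort(spec: Optional[CohortSpec] = None,
                    seed: Union[int, np.random.Generator, None] = None
                    ) -> pd.DataFrame:
    """Draw one synthetic cohort as a canonical cohort DataFrame.

    Sex counts are fixed (not resampled); draws are fully determined by
    `seed` (an int or an existing numpy Generator).
    """
    if spec is None:
        spec = cross_sectional_spec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for sex, mom in ((Sex.MALE, spec.men), (Sex.FEMALE, spec.women)):
        if mom.n == 0:
            continue
        if spec.wh_corr != 0:
            w, h = _truncated_bivariate(
                rng, mom.n, mom.weight_mean, mom.weight_sd,
                mom.height_mean, mom.height_sd, spec.wh_corr,
                spec.weight_range, spec.height_range,
            )
        else:
            w = _truncated_normal(rng, mom.n, mom.weight_mean, mom.weight_sd,
                                  spec.weight_range, "weight")
            h = _truncated_normal(rng, mom.n, mom.height_mean, mom.height_sd,
                                  spec.height_range, "height")
        a = _truncated_normal(rng, mom.n, mom.age_mean, mom.age_sd,
                              spec.age_range, "age")
        g = sex.indicator
        bmr = (spec.coeff_intercept + spec.coeff_weight * w + spec.coeff_gender * g
               + rng.normal(0.0, spec.residual_sd, size=mom.n))
        frames.append(pd.DataFrame({
            "sex": sex.value, "age": a, "weight": w, "height": h,
            "bmr_measured": bmr,
        }))
    if not frames:
        raise ValueError("spec has zero subjects")
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"{spec.id_prefix}{i + 1:04d}" for i in range(len(df))])
    return df[COHORT_COLUMNS]


def generate_validation_cohort(seed: Union[int, np.random.Generator, None] = None,
                               **overrides) -> pd.DataFrame:
    """Convenience wrapper for the cross-validation preset."""
    return generate_cohort(cross_validation_spec(**overrides), seed=seed)


@dataclass(frozen=True)
class GasTraceSpec:
    """Parameters of one synthetic hood session.

    The steady-state level encodes `bmr_true`; the transient multiplies the
    signal by (1 + transient_amp * exp(-t / tau)) with tau chosen so the
    transient has decayed to e^-5 (<1%) by `transient_minutes`.
    """

    bmr_true: float  # kJ/d
    rq: float = 0.85  # VCO2/VO2
    noise_cv: float = 0.03  # per-sample multiplicative noise
    transient_minutes: float = 4.0
    transient_amp: float = 0.15
    duration_s: float = 1800.0
    interval_s: float = 5.0

    def __post_init__(self):
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError("RQ must lie in [0.7, 1.0]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.bmr_true <= 0:
            raise ValueError("bmr_true must be positive")

    @property
    def vo2_target(self) -> float:
        """Steady-state VO2 (L/min) whose Weir energy equals bmr_true."""
        kcal_min = self.bmr_true / (MIN_PER_DAY * KJ_PER_KCAL)
        return kcal_min / (WEIR_VO2_KCAL_PER_L + WEIR_VCO2_KCAL_PER_L * self.rq)

    @property
    def vco2_target(self) -> float:
        return self.rq * self.vo2_target


def generate_gas_series(spec: GasTraceSpec,
                        seed: Union[int, np.random.Generator, None] = None
                        ) -> GasExchangeSeries:
    """Synthesize a hood trace whose steady state encodes spec.bmr_true."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, spec.duration_s, spec.interval_s)
    shape = np.ones_like(t)
    if spec.transient_amp != 0 and spec.transient_minutes > 0:
        tau = spec.transient_minutes * 60.0 / 5.0
        shape = 1.0 + spec.transient_amp * np.exp(-t / tau)
    vo2 = spec.vo2_target * shape
    vco2 = spec.vco2_target * shape
    if spec.noise_cv > 0:
        vo2 = vo2 * (1.0 + rng.normal(0.0, spec.noise_cv, size=t.shape))
        vco2 = vco2 * (1.0 + rng.normal(0.0, spec.noise_cv, size=t.shape))
    return GasExchangeSeries(t, np.clip(vo2, 0.0, None), np.clip(vco2, 0.0, None))
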