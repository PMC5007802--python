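"""Indirect calorimetry: ventilated-hood gas exchange to measured BMR.

The processing chain mirrors the standard hood protocol: a 30-min trace of
VO2/VCO2 sampled every 5 s, the first 5 min discarded as habituation, then
the most stable 10-min window (coefficient of variation of both gases below
a threshold) averaged and converted to energy expenditure with the
abbreviated Weir equation (no urinary-nitrogen correction):

    EE (kcal/min) = 3.941 * VO2 (L/min) + 1.106 * VCO2 (L/min)

expressed throughout in kJ/d (1 kcal = 4.184 kJ, 1440 min/d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WEIR_VO2_KCAL_PER_L",
    "WEIR_VCO2_KCAL_PER_L",
    "KJ_PER_KCAL",
    "GasExchangeSeries",
    "SteadyStateWindow",
    "NoSteadyStateError",
    "weir_bmr",
    "discard_habituation",
    "select_steady_state",
    "series_to_bmr",
]

WEIR_VO2_KCAL_PER_L = 3.941
WEIR_VCO2_KCAL_PER_L = 1.106
KJ_PER_KCAL = 4.184
MIN_PER_DAY = 1440.0

DEFAULT_DISCARD_S = 300.0  # first 5 min of habituation
DEFAULT_WINDOW_S = 600.0  # 10-min steady-state window
DEFAULT_CV_MAX = 0.10


def weir_bmr(vo2, vco2):
    """Energy expenditure (kJ/d) from VO2 and VCO2 rates in L/min (STPD).

    Abbreviated Weir equation without protein correction; linear in both
    arguments, vectorises over arrays.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("VO2 and VCO2 must be non-negative")
    kcal_min = WEIR_VO2_KCAL_PER_L * vo2 + WEIR_VCO2_KCAL_PER_L * vco2
    out = kcal_min * MIN_PER_DAY * KJ_PER_KCAL
    return float(out) if out.ndim == 0 else out


@dataclass
class GasExchangeSeries:
    """Uniformly sampled VO2/VCO2 trace; t in seconds from session start."""

    t: np.ndarray  # s
    vo2: np.ndarray  # L/min
    vco2: np.ndarray  # L/min

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (len(self.t) == len(self.vo2) == len(self.vco2)):
            raise ValueError("t, vo2 and vco2 must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6 * dt[0]):
                raise ValueError("sampling must be uniform")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("VO2 and VCO2 must be non-negative")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def interval(self) -> float:
        if self.n < 2:
            raise ValueError("interval undefined for series with < 2 samples")
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Session length in seconds, counting the final sampling interval."""
        return float(self.t[-1] - self.t[0]) + self.interval


@dataclass(frozen=True)
class SteadyStateWindow:
    start: float  # s, inclusive
    end: float  # s, exclusive
    cv_vo2: float
    cv_vco2: float

    @property
    def cv_sum(self) -> float:
        return self.cv_vo2 + self.cv_vco2


class NoSteadyStateError(RuntimeError):
    """No window met the CV criterion; carries the best candidate found."""

    def __init__(self, best: Optional[SteadyStateWindow], cv_max: float):
        self.best = best
        self.cv_max = cv_max
        detail = (
            f"best window [{best.start:.0f}, {best.end:.0f}) s had "
            f"CV(VO2)={best.cv_vo2:.3f}, CV(VCO2)={best.cv_vco2:.3f}"
            if best is not None
            else "series too short for any window"
        )
        super().__init__(f"no steady-state window with CV <= {cv_max}: {detail}")


def discard_habituation(series: GasExchangeSeries,
                        discard: float = DEFAULT_DISCARD_S) -> GasExchangeSeries:
    """Drop the habituation period: keep samples with t >= discard seconds."""
    if discard < 0:
        raise ValueError("discard must be non-negative")
    if discard == 0:
        return series
    if series.n == 0 or series.duration <= discard:
        raise ValueError(
            f"series duration {series.duration if series.n else 0:.0f} s "
            f"does not exceed the {discard:.0f} s discard period"
        )
    keep = series.t >= discard
    return GasExchangeSeries(series.t[keep], series.vo2[keep], series.vco2[keep])


def _window_cvs(x: np.ndarray, width: int) -> np.ndarray:
    """Sample CV (ddof=1) of every sliding window of `width` samples."""
    views = sliding_window_view(x, width)
    means = views.mean(axis=1)
    sds = views.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(means > 0, sds / means, np.inf)


def select_steady_state(series: GasExchangeSeries,
                        window: float = DEFAULT_WINDOW_S,
                        cv_max: float = DEFAULT_CV_MAX) -> SteadyStateWindow:
    """Most stable window of the given length (seconds).

    Every start position (stepping one sampling interval) is scored by the
    within-window CV of VO2 and of VCO2; windows where both CVs are at or
    below `cv_max` qualify, and the qualifying window minimising
    cv_vo2 + cv_vco2 is returned (earliest start on ties). Windows are
    half-open in time: [start, start + window).
    """
    if series.n < 2:
        raise ValueError("series too short for steady-state selection")
    dt = series.interval
    width = int(round(window / dt))
    if width < 2:
        raise ValueError(f"window {window} s spans fewer than 2 samples at dt={dt}")
    if width > series.n:
        raise NoSteadyStateError(None, cv_max)
    cv_o = _window_cvs(series.vo2, width)
    cv_c = _window_cvs(series.vco2, width)
    total = cv_o + cv_c

    def make(i: int) -> SteadyStateWindow:
        return SteadyStateWindow(
            start=float(series.t[i]),
            end=float(series.t[i] + width * dt),
            cv_vo2=float(cv_o[i]),
            cv_vco2=float(cv_c[i]),
        )

    ok = (cv_o <= cv_max) & (cv_c <= cv_max)
    if not ok.any():
        raise NoSteadyStateError(make(int(np.argmin(total))), cv_max)
    idx = np.flatnonzero(ok)
    best = idx[np.argmin(total[idx])]  # argmin returns first index on ties
    return make(int(best))


def series_to_bmr(series: GasExchangeSeries,
                  discard: float = DEFAULT_DISCARD_S,
                  window: float = DEFAULT_WINDOW_S,
                  cv_max: float = DEFAULT_CV_MAX,
                  average_all_windows: bool = False,
                  ) -> Tuple[float, SteadyStateWindow]:
    """Measured BMR (kJ/d) from a hood trace.

    Discards the habituation period, selects the steady-state window, and
    feeds the window-mean VO2/VCO2 to the Weir equation. With
    `average_all_windows`, the Weir BMR is instead averaged over every
    qualifying window (the returned window is still the single best one).
    """
    trimmed = discard_habituation(series, discard)
    win = select_steady_state(trimmed, window, cv_max)
    width = int(round(window / trimmed.interval))
    if average_all_windows:
        cv_o = _window_cvs(trimmed.vo2, width)
        cv_c = _window_cvs(trimmed.vco2, width)
        ok = (cv_o <= cv_max) & (cv_c <= cv_max)
        views_o = sliding_window_view(trimmed.vo2, width)
        views_c = sliding_window_view(trimmed.vco2, width)
        bmr = float(np.mean(weir_bmr(views_o[ok].mean(axis=1), views_c[ok].mean(axis=1))))
        return bmr, win
    m = (trimmed.t >= win.start) & (trimmed.t < win.end)
    return float(weir_bmr(trimmed.vo2[m].mean(), trimmed.vco2[m].mean())), win
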