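"""Registry of anthropometric BMR prediction equations (kJ/d).

Seven equations are built in: the Singapore equation (weight + gender),
Harris-Benedict, Henry (Oxford, three age bands per sex), Liu, Yang,
Mifflin and Owen. Each equation is a set of sex-specific, age-banded
linear forms

    BMR = intercept + w*weight(kg) + h*height(cm) + a*age(years)

with coefficients stored exactly as published. Henry's bands are dispatched
half-open — [18, 30), [30, 60), [60, 70] — with the top band closed; ages
outside every band raise :class:`BandDispatchError` unless nearest-band
extrapolation is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .subjects import Sex, SubjectRecord, as_frame

__all__ = [
    "Band",
    "PredictionEquation",
    "BandDispatchError",
    "builtin_equations",
    "get_equation",
    "predict_bmr",
    "registry_to_records",
    "registry_from_records",
]

#: Nominal adult age range covered by single-band ("Adult") equations.
ADULT_AGE_MIN = 18.0
ADULT_AGE_MAX = 120.0


class BandDispatchError(ValueError):
    """Raised when a subject's age falls outside every band of an equation."""


@dataclass(frozen=True)
class Band:
    sex: Sex
    age_min: float
    age_max: float
    intercept: float  # kJ/d
    w: float = 0.0  # kJ/d per kg
    h: float = 0.0  # kJ/d per cm
    a: float = 0.0  # kJ/d per year

    def evaluate(self, weight, height, age):
        return self.intercept + self.w * weight + self.h * height + self.a * age


@dataclass(frozen=True)
class PredictionEquation:
    name: str
    bands: tuple[Band, ...]

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        for sex in Sex:
            sx = self._sex_bands(sex)
            for b1, b2 in zip(sx, sx[1:]):
                if b1.age_max > b2.age_min:
                    raise ValueError(
                        f"{self.name}: overlapping {sex.value} age bands "
                        f"[{b1.age_min},{b1.age_max}) and [{b2.age_min},{b2.age_max})"
                    )

    def _sex_bands(self, sex: Sex) -> list[Band]:
        return sorted((b for b in self.bands if b.sex is sex), key=lambda b: b.age_min)

    def _dispatch(self, sex: Sex, age: float, extrapolate: bool) -> Band:
        bands = self._sex_bands(sex)
        if not bands:
            raise BandDispatchError(f"{self.name}: no bands for sex {sex.value}")
        top = bands[-1]
        for b in bands:
            if b.age_min <= age < b.age_max or (b is top and age == b.age_max):
                return b
        if extrapolate:
            return min(bands, key=lambda b: min(abs(age - b.age_min), abs(age - b.age_max)))
        raise BandDispatchError(
            f"{self.name}: age {age} outside all {sex.value} bands "
            f"({', '.join(f'[{b.age_min},{b.age_max}]' for b in bands)})"
        )

    def predict_one(self, sex, age: float, weight: float, height: float,
                    extrapolate: bool = False) -> float:
        band = self._dispatch(Sex.parse(sex), age, extrapolate)
        return float(band.evaluate(weight, height, age))

    def predict(self, cohort, extrapolate: bool = False) -> np.ndarray:
        """Vectorised prediction over a cohort (DataFrame or record list), kJ/d."""
        df = as_frame(cohort)
        out = np.full(len(df), np.nan)
        sex = df["sex"].to_numpy()
        age = df["age"].to_numpy(dtype=float)
        weight = df["weight"].to_numpy(dtype=float)
        height = df["height"].to_numpy(dtype=float)
        for s in Sex:
            bands = self._sex_bands(s)
            if not bands:
                continue
            top = bands[-1]
            sel = sex == s.value
            for b in bands:
                in_band = (age >= b.age_min) & (
                    (age < b.age_max) | ((b is top) & (age == b.age_max))
                )
                m = sel & in_band & np.isnan(out)
                out[m] = b.evaluate(weight[m], height[m], age[m])
        if np.isnan(out).any():
            if extrapolate:
                for i in np.flatnonzero(np.isnan(out)):
                    out[i] = self.predict_one(sex[i], age[i], weight[i], height[i],
                                              extrapolate=True)
            else:
                bad = df.loc[np.isnan(out), ["id", "sex", "age"]]
                raise BandDispatchError(
                    f"{self.name}: ages outside all bands for subjects "
                    f"{bad['id'].tolist()} (ages {bad['age'].tolist()})"
                )
        return out


def _adult(name: str, men: tuple, women: tuple) -> PredictionEquation:
    """Single 'Adult' band per sex; tuples are (intercept, w, h, a)."""
    def band(sex, c):
        return Band(sex, ADULT_AGE_MIN, ADULT_AGE_MAX, c[0], c[1], c[2], c[3])
    return PredictionEquation(name, (band(Sex.MALE, men), band(Sex.FEMALE, women)))


def builtin_equations() -> list[PredictionEquation]:
    """The seven published equations, coefficients in kJ/d as printed."""
    henry = PredictionEquation(
        "Henry",
        (
            Band(Sex.MALE, 18, 30, 473, w=60.0, h=13.1),
            Band(Sex.MALE, 30, 60, -574, w=47.6, h=22.6),
            Band(Sex.MALE, 60, 70, -1070, w=47.8, h=22.6),
            Band(Sex.FEMALE, 18, 30, -1180, w=43.3, h=25.7),
            Band(Sex.FEMALE, 30, 60, -49, w=34.2, h=21.0),
            Band(Sex.FEMALE, 60, 70, 45, w=35.6, h=17.6),
        ),
    )
    return [
        _adult("Singapore", (2788, 52.6, 0, 0), (1960, 52.6, 0, 0)),
        _adult("HB", (278, 57.5, 20.9, -28.2), (2783, 40.0, 7.7, -19.5)),
        henry,
        _adult("Liu", (227, 58.1, 17.4, -14.4), (-243, 58.1, 17.4, -14.4)),
        _adult("Yang", (877, 89, 0, 0), (277, 89, 0, 0)),
        _adult("Mifflin", (21, 41.8, 26.2, -20.6), (-674, 41.8, 26.2, -20.6)),
        _adult("Owen", (3678, 42.7, 0, 0), (3326, 30.0, 0, 0)),
    ]


def get_equation(name: str) -> PredictionEquation:
    for eq in builtin_equations():
        if eq.name.lower() == name.lower():
            return eq
    raise KeyError(f"no built-in equation named {name!r}")


def predict_bmr(eq: PredictionEquation, subject: SubjectRecord,
                extrapolate: bool = False) -> float:
    """Predicted BMR (kJ/d) for one subject."""
    return eq.predict_one(subject.sex, subject.age, subject.weight, subject.height,
                          extrapolate=extrapolate)


def registry_to_records(eqs: Iterable[PredictionEquation]) -> list[dict]:
    """Flatten a registry to one mapping per band (config-file form)."""
    out = []
    for eq in eqs:
        for b in eq.bands:
            out.append(
                {
                    "name": eq.name,
                    "sex": b.sex.value,
                    "age_min": float(b.age_min),
                    "age_max": float(b.age_max),
                    "intercept": float(b.intercept),
                    "w": float(b.w),
                    "h": float(b.h),
                    "a": float(b.a),
                }
            )
    return out


def registry_from_records(records: Sequence[dict]) -> list[PredictionEquation]:
    by_name: dict[str, list[Band]] = {}
    order: list[str] = []
    for r in records:
        name = r["name"]
        if name not in by_name:
            by_name[name] = []
            order.append(name)
        by_name[name].append(
            Band(
                sex=Sex.parse(r["sex"]),
                age_min=float(r["age_min"]),
                age_max=float(r["age_max"]),
                intercept=float(r["intercept"]),
                w=float(r.get("w", 0.0)),
                h=float(r.get("h", 0.0)),
                a=float(r.get("a", 0.0)),
            )
        )
    return [PredictionEquation(name, tuple(by_name[name])) for name in order]
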