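"""Subject records, cohort tables and body-mass-index helpers.

A cohort is carried either as a list of :class:`SubjectRecord` or as a
pandas DataFrame with columns ``id, sex, age, weight, height, bmr_measured``
(sex coded ``"M"``/``"F"``, weight in kg, height in cm, BMR in kJ/d,
``bmr_measured`` NaN when the subject was not measured). The two forms are
interchangeable via :func:`to_frame` / :func:`from_frame`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "SubjectRecord",
    "BmiCategory",
    "BmiClass",
    "compute_bmi",
    "classify_bmi",
    "bmi_two_way",
    "to_frame",
    "from_frame",
    "as_frame",
    "validate_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["id", "sex", "age", "weight", "height", "bmr_measured"]

#: Default lower age bound for an adult cohort (years).
MIN_ADULT_AGE = 18.0


class Sex(str, enum.Enum):
    """Biological sex, coded as in the study (men = 1, women = 0)."""

    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, value: Union["Sex", str]) -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in {"m", "male", "man", "men", "1"}:
            return cls.MALE
        if v in {"f", "female", "woman", "women", "0"}:
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code {value!r} (expected M or F)")

    @property
    def indicator(self) -> int:
        """Gender dummy used by the regression model: men = 1, women = 0."""
        return 1 if self is Sex.MALE else 0


@dataclass
class SubjectRecord:
    """One participant: anthropometry plus an optional measured BMR (kJ/d)."""

    id: str
    sex: Sex
    age: float  # years
    weight: float  # kg
    height: float  # cm
    bmr_measured: Optional[float] = None  # kJ/d

    def __post_init__(self) -> None:
        self.sex = Sex.parse(self.sex)
        if not self.weight > 0:
            raise ValueError(f"subject {self.id}: weight must be > 0, got {self.weight}")
        if not self.height > 0:
            raise ValueError(f"subject {self.id}: height must be > 0, got {self.height}")
        if not self.age >= 0:
            raise ValueError(f"subject {self.id}: age must be non-negative, got {self.age}")
        if self.bmr_measured is not None and (
            isinstance(self.bmr_measured, float) and math.isnan(self.bmr_measured)
        ):
            self.bmr_measured = None

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)

    @property
    def gender(self) -> int:
        return self.sex.indicator


class BmiCategory(str, enum.Enum):
    NOT_OVERWEIGHT = "not_overweight"  # BMI <= 23.0
    OVERWEIGHT = "overweight"  # 23.0 < BMI <= 27.5
    OBESE = "obese"  # BMI > 27.5


#: Asian-population cut-offs: overweight above 23.0 kg/m2, obese above 27.5.
BMI_OVERWEIGHT_CUT = 23.0
BMI_OBESE_CUT = 27.5


@dataclass(frozen=True)
class BmiClass:
    value: float  # kg/m2
    category: BmiCategory


def compute_bmi(weight, height):
    """Body mass index, kg/m^2, from weight in kg and height in cm.

    Accepts scalars or numpy arrays; raises on non-positive input.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    bmi = w / (h / 100.0) ** 2
    if bmi.ndim == 0:
        return float(bmi)
    return bmi


def classify_bmi(bmi: float) -> BmiClass:
    """Three-way classification at the Asian cut-offs (23.0 / 27.5 kg/m^2).

    Boundaries are inclusive below: 23.0 is not overweight, 27.5 is
    overweight (not obese).
    """
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi <= BMI_OVERWEIGHT_CUT:
        cat = BmiCategory.NOT_OVERWEIGHT
    elif bmi <= BMI_OBESE_CUT:
        cat = BmiCategory.OVERWEIGHT
    else:
        cat = BmiCategory.OBESE
    return BmiClass(value=float(bmi), category=cat)


def bmi_two_way(bmi, cut: float = BMI_OVERWEIGHT_CUT):
    """Two-way split used for stratified accuracy tables: True where BMI > cut.

    A BMI exactly at the cut falls in the lower ("<= cut") stratum.
    """
    return np.asarray(bmi, dtype=float) > cut


def to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "sex": r.sex.value,
            "age": r.age,
            "weight": r.weight,
            "height": r.height,
            "bmr_measured": np.nan if r.bmr_measured is None else r.bmr_measured,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for row in df.itertuples(index=False):
        bmr = getattr(row, "bmr_measured", None)
        if bmr is not None and isinstance(bmr, float) and math.isnan(bmr):
            bmr = None
        records.append(
            SubjectRecord(
                id=str(row.id),
                sex=Sex.parse(row.sex),
                age=float(row.age),
                weight=float(row.weight),
                height=float(row.height),
                bmr_measured=bmr,
            )
        )
    return records


def as_frame(cohort: Union[pd.DataFrame, Sequence[SubjectRecord]]) -> pd.DataFrame:
    """Coerce either cohort representation to the canonical DataFrame."""
    if isinstance(cohort, pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS[:-1] if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        df = cohort.copy()
        if "bmr_measured" not in df.columns:
            df["bmr_measured"] = np.nan
        df["sex"] = [Sex.parse(s).value for s in df["sex"]]
        return df[COHORT_COLUMNS]
    return to_frame(cohort)


def validate_cohort(df: pd.DataFrame, min_age: float = MIN_ADULT_AGE) -> pd.DataFrame:
    """Check positivity and the adult age bound; returns the frame unchanged."""
    df = as_frame(df)
    if (df["weight"] <= 0).any():
        bad = df.loc[df["weight"] <= 0, "id"].tolist()
        raise ValueError(f"non-positive weight for subjects {bad}")
    if (df["height"] <= 0).any():
        bad = df.loc[df["height"] <= 0, "id"].tolist()
        raise ValueError(f"non-positive height for subjects {bad}")
    if (df["age"] < min_age).any():
        bad = df.loc[df["age"] < min_age, "id"].tolist()
        raise ValueError(f"age below {min_age} for subjects {bad}")
    return df
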