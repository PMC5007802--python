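"""Readers and writers for the package's plain-text formats.

All files are UTF-8 CSV with comma separator and dot decimal, or YAML/JSON
for configuration. Units are kJ/d internally; kcal conversion happens only
at render time.

Formats:
- cohort CSV: ``id,sex,age,weight_kg,height_cm,bmr_kj_d`` with sex M/F and
  ``bmr_kj_d`` optionally blank;
- gas CSV: ``t_s,vo2_l_min,vco2_l_min`` at uniform (default 5 s) cadence;
- equation registry YAML: a list of band records
  (name, sex, age_min, age_max, intercept, w, h, a);
- evaluation report: CSV rounded the way the study prints (integer kJ/d and
  percent), or JSON at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .agreement import EquationEvaluation
from .calorimetry import GasExchangeSeries
from .equations import PredictionEquation, registry_from_records, registry_to_records
from .subjects import COHORT_COLUMNS, Sex

__all__ = [
    "CohortCsvError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_gas_csv",
    "write_gas_csv",
    "read_equations",
    "write_equations",
    "write_report",
    "read_report_json",
    "write_manifest",
]

COHORT_CSV_COLUMNS = ["id", "sex", "age", "weight_kg", "height_cm", "bmr_kj_d"]
GAS_CSV_COLUMNS = ["t_s", "vo2_l_min", "vco2_l_min"]
KJ_PER_KCAL = 4.184


class CohortCsvError(ValueError):
    """Parse/validation failure with the offending row number (1-based data row)."""


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV into the canonical cohort frame."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"id": str}, encoding="utf-8")
    missing = [c for c in COHORT_CSV_COLUMNS[:-1] if c not in raw.columns]
    if missing:
        raise CohortCsvError(f"{path}: missing required columns {missing}")
    if "bmr_kj_d" not in raw.columns:
        raw["bmr_kj_d"] = np.nan
    out = pd.DataFrame()
    out["id"] = raw["id"].astype(str)
    sexes = []
    for i, v in enumerate(raw["sex"], start=1):
        try:
            sexes.append(Sex.parse(v).value)
        except ValueError as err:
            raise CohortCsvError(f"{path} row {i}: {err}") from err
    out["sex"] = sexes
    for src, dst, positive in (("age", "age", False), ("weight_kg", "weight", True),
                               ("height_cm", "height", True)):
        vals = pd.to_numeric(raw[src], errors="coerce")
        for i, (orig, v) in enumerate(zip(raw[src], vals), start=1):
            if np.isnan(v):
                raise CohortCsvError(f"{path} row {i}: non-numeric {src} {orig!r}")
            if positive and v <= 0:
                raise CohortCsvError(f"{path} row {i}: {src} must be positive, got {v}")
        out[dst] = vals.astype(float)
    bmr = pd.to_numeric(raw["bmr_kj_d"], errors="coerce")
    bad = bmr.isna() & raw["bmr_kj_d"].notna() & (raw["bmr_kj_d"].astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad)[0]) + 1
        raise CohortCsvError(f"{path} row {i}: non-numeric bmr_kj_d "
                             f"{raw['bmr_kj_d'].iloc[i - 1]!r}")
    out["bmr_measured"] = bmr.astype(float)
    return out[COHORT_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path: Union[str, Path]) -> None:
    df = cohort.rename(columns={"weight": "weight_kg", "height": "height_cm",
                                "bmr_measured": "bmr_kj_d"})
    df[COHORT_CSV_COLUMNS].to_csv(path, index=False, encoding="utf-8",
                                  float_format="%.10g")


def read_gas_csv(path: Union[str, Path], cadence_tol: float = 1e-6
                 ) -> GasExchangeSeries:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in GAS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=max(cadence_tol, 1e-12)):
            raise ValueError(f"{path}: non-uniform sampling cadence")
    return GasExchangeSeries(t, df["vo2_l_min"].to_numpy(dtype=float),
                             df["vco2_l_min"].to_numpy(dtype=float))


def write_gas_csv(series: GasExchangeSeries, path: Union[str, Path]) -> None:
    pd.DataFrame({
        "t_s": series.t, "vo2_l_min": series.vo2, "vco2_l_min": series.vco2,
    }).to_csv(path, index=False, encoding="utf-8", float_format="%.10g")


def read_equations(path: Union[str, Path]) -> list[PredictionEquation]:
    with open(path, encoding="utf-8") as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a list of band records")
    return registry_from_records(records)


def write_equations(eqs: Iterable[PredictionEquation], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry_to_records(eqs), fh, sort_keys=False)


_ROUND_COLS_INT = ["mean_pred", "sd_pred", "bias", "sd_diff", "loa_low", "loa_high",
                   "pct_under", "pct_accurate", "pct_over",
                   "pct_under_le", "pct_accurate_le", "pct_over_le",
                   "pct_under_gt", "pct_accurate_gt", "pct_over_gt"]


def write_report(evaluation: EquationEvaluation, path: Union[str, Path],
                 fmt: str = "csv", kcal: bool = False) -> None:
    """Write a ranked evaluation; CSV rounds to report precision, JSON keeps all.

    With ``kcal`` the energy columns are divided by 4.184 at render time.
    """
    if not evaluation.reports:
        raise ValueError("nothing to write: evaluation has no reports")
    df = evaluation.to_frame()
    if kcal:
        for c in ("mean_pred", "sd_pred", "bias", "sd_diff", "loa_low", "loa_high"):
            df[c] = df[c] / KJ_PER_KCAL
    if fmt == "csv":
        out = df.copy()
        for c in _ROUND_COLS_INT:
            out[c] = out[c].round(0).astype("Int64")
        out["r2"] = out["r2"].round(2)
        out["ba_slope"] = out["ba_slope"].round(3)
        out.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "json":
        payload = {
            "reports": [r.to_dict() for r in evaluation.reports],
            "breakdowns": [b.to_dict() for b in evaluation.breakdowns],
            "skipped": evaluation.skipped,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report_json(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_manifest(path: Union[str, Path], **entries) -> None:
    """Record config + seed + package version so a run can be replayed."""
    from . import __version__

    payload = {"bmrkit_version": __version__, "rng": "numpy PCG64 via default_rng",
               **entries}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
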