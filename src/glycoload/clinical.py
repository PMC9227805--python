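"""Glycemic-control markers and the stratification/filter variables.

HOMA-IR follows the Matthews mg/dL convention,
``fasting glucose (mg/dL) × fasting insulin (mU/L) / 405``, the formulation
used throughout the pediatric insulin-resistance literature. Weight status is
read off the BMI z-score (< 1 normal weight, ≥ 1 overweight, ≥ 2 obese), with
the two-level analysis stratum pooling overweight and obese (OW). Physical
activity is categorized as inactive (0 min/week), insufficiently active
(< 300) or active (≥ 300); self-reports above 2100 min/week are treated as
low-quality and set missing. Adolescents who self-report diabetes are
excluded before any modelling.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

GLUCOSE_RANGE = (30.0, 400.0)  # mg/dL plausibility window
INSULIN_RANGE = (0.0, 300.0)  # mU/L plausibility window
PA_ACTIVE_MIN = 300.0  # min/week
PA_QUALITY_MAX = 2100.0  # min/week; above → low-quality report, set missing

MARKERS = ["hba1c", "insulin", "homa_ir"]

STUDENT_COLUMNS = [
    "student_id",
    "sex",
    "age_years",
    "maturation",
    "pa_min_week",
    "bmi_z",
    "diabetes_self_report",
    "glucose_mg_dl",
    "insulin_mU_L",
    "hba1c_pct",
    "stratum",
    "psu",
    "weight",
]


def homa_ir(glucose_mg_dl, insulin_mU_L):
    """HOMA-IR = glucose (mg/dL) × insulin (mU/L) / 405.

    Accepts scalars or arrays. Inputs outside the plausibility windows
    (glucose 30–400 mg/dL, insulin 0–300 mU/L, both strictly positive) yield
    a missing marker with a logged reason rather than an exception, mirroring
    how lost/implausible assays are accounted as missing data.
    """
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_mU_L, dtype=float)
    ok = (g >= GLUCOSE_RANGE[0]) & (g <= GLUCOSE_RANGE[1]) & (i > 0) & (i <= INSULIN_RANGE[1])
    n_bad = int(np.sum(~ok & ~(np.isnan(g) | np.isnan(i))))
    if n_bad:
        logger.warning("homa_ir: %d input pair(s) outside plausible ranges set missing", n_bad)
    out = np.where(ok, g * i / 405.0, np.nan)
    if np.isscalar(glucose_mg_dl) and np.isscalar(insulin_mU_L):
        return float(out)
    return out


def weight_status(bmi_z):
    """Three-level weight status from the BMI z-score.

    Returns ``"normal"`` (< 1), ``"overweight"`` (≥ 1) or ``"obese"`` (≥ 2);
    arrays in, arrays out.
    """
    z = np.asarray(bmi_z, dtype=float)
    out = np.select([z >= 2.0, z >= 1.0], ["obese", "overweight"], default="normal")
    out = np.where(np.isnan(z), None, out)
    return out.item() if np.isscalar(bmi_z) else out


def weight_stratum(bmi_z):
    """Two-level analysis stratum: NW (< 1) vs OW (overweight ∪ obese, ≥ 1)."""
    z = np.asarray(bmi_z, dtype=float)
    out = np.where(z >= 1.0, "OW", "NW")
    out = np.where(np.isnan(z), None, out)
    return out.item() if np.isscalar(bmi_z) else out


PA_CATEGORIES = ["inactive", "insufficiently_active", "active"]


def pa_category(pa_min_week):
    """Physical-activity category, or None for absent/low-quality reports.

    0 → inactive; (0, 300) → insufficiently_active; [300, 2100] → active;
    > 2100 min/week → None (disregarded as low quality). Negative minutes are
    a validation error.
    """
    scalar = np.isscalar(pa_min_week) or pa_min_week is None
    x = np.asarray(np.nan if pa_min_week is None else pa_min_week, dtype=float)
    if np.any(x < 0):
        raise ValueError("pa_min_week must be non-negative")
    out = np.select(
        [np.isnan(x) | (x > PA_QUALITY_MAX), x == 0, x < PA_ACTIVE_MIN],
        [None, "inactive", "insufficiently_active"],
        default="active",
    )
    return out.item() if scalar else out


def exclusion_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop self-reported diabetics; return (retained, exclusion log).

    Retained rows are unaltered (only membership changes);
    retained + excluded = input count. The log is a ``reason,count`` table.
    Model-specific missingness is handled listwise per model downstream, not
    here.
    """
    if "diabetes_self_report" not in records.columns:
        raise SchemaError("records lack a diabetes_self_report column")
    flag = records["diabetes_self_report"].fillna(0).astype(float).astype(bool)
    retained = records.loc[~flag]
    log = pd.DataFrame({"reason": ["diabetes_self_report"], "count": [int(flag.sum())]})
    return retained, log


def eligibility_accounting(
    enrolled: int, ineligible_counts: Mapping[str, int]
) -> dict:
    """Enrollment arithmetic: eligible count and ineligible percentage.

    Returns ``{"enrolled", "ineligible", "eligible", "ineligible_pct"}`` with
    the percentage rounded to one decimal as conventionally printed.
    """
    ineligible = int(sum(ineligible_counts.values()))
    eligible = int(enrolled) - ineligible
    pct = round(100.0 * ineligible / enrolled, 1)
    return {
        "enrolled": int(enrolled),
        "ineligible": ineligible,
        "eligible": eligible,
        "ineligible_pct": pct,
    }


def prepare_students(students: pd.DataFrame) -> pd.DataFrame:
    """Derive homa_ir, weight status/stratum and pa_category columns.

    HOMA-IR is present iff both glucose and insulin are present and in range;
    pa_category is missing iff minutes are missing or above the quality cap.
    """
    missing = [c for c in STUDENT_COLUMNS if c not in students.columns]
    if missing:
        raise SchemaError(f"students table missing columns {missing}")
    df = students.copy()
    for col in ["age_years", "maturation", "pa_min_week", "bmi_z", "glucose_mg_dl", "insulin_mU_L", "hba1c_pct", "weight"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["homa_ir"] = homa_ir(df["glucose_mg_dl"].to_numpy(), df["insulin_mU_L"].to_numpy())
    df["weight_status"] = weight_status(df["bmi_z"].to_numpy())
    df["weight_stratum"] = weight_stratum(df["bmi_z"].to_numpy())
    df["pa_category"] = pa_category(df["pa_min_week"].to_numpy())
    df["insulin"] = df["insulin_mU_L"]
    df["hba1c"] = df["hba1c_pct"]
    df["female"] = (df["sex"].astype(str).str.lower() == "female").astype(float)
    return df


def read_students(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"student_id": str, "stratum": str, "psu": str}, comment="#")
    missing = [c for c in STUDENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df
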