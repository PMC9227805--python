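"""Per-occasion, daily, and average-of-occasions glycemic index and load.

For one student-day with consumed foods f (glycemic carbohydrate c_f grams,
GI g_f):

* daily GI:   DGI  = Σ c_f g_f / Σ c_f        (carbohydrate-weighted mean)
* daily GL:   DGL  = Σ c_f g_f / 100
* occasion GI/GL: the same two formulas restricted to one eating occasion
* AvGI = unweighted mean of occasion GIs over occasions with carbohydrate
* AvGL = unweighted mean of occasion GLs over all reported occasions
  (configurable to carbohydrate-bearing occasions only)

AvGI/AvGL summarize within-day "peaks" that the whole-day weighting of
DGI/DGL averages away. The identities DGL = DGI × Σc/100 and
DGL = Σ occasion GL hold exactly and are asserted in the test suite.
Aggregation order is fixed (sorted by student, occasion order, food id) so
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .food_gi import FoodItem, food_table_frame

RECALL_COLUMNS = ["student_id", "occasion_id", "occasion_order", "food_id", "amount_g"]


@dataclass
class ConsumedFood:
    """One food eaten at one occasion, with resolved glycemic carbohydrate and GI."""

    student_id: str
    occasion_id: str
    occasion_order: int
    food_id: str
    amount_g: float
    glycemic_carb_g: float
    gi: float

    def __post_init__(self):
        if self.amount_g <= 0:
            raise ValueError(f"amount_g must be positive, got {self.amount_g}")
        if not (0 <= self.glycemic_carb_g <= self.amount_g):
            raise ValueError(
                f"glycemic_carb_g {self.glycemic_carb_g} outside [0, amount_g={self.amount_g}]"
            )


@dataclass
class OccasionMetrics:
    occasion_id: str
    occasion_order: int
    gi: Optional[float]  # absent when the occasion has no glycemic carbohydrate
    gl: float
    carb_g: float


@dataclass
class DayMetrics:
    student_id: str
    dgi: Optional[float]
    dgl: float
    av_gi: Optional[float]
    av_gl: float
    n_occasions: int
    n_carb_occasions: int
    total_glycemic_carb_g: float


def occasion_gi(foods: Sequence[ConsumedFood]) -> Optional[float]:
    """Carbohydrate-weighted mean GI of one occasion; None when carbohydrate is 0."""
    if not foods:
        raise ValueError("occasion_gi requires a non-empty food list")
    carb = sum(f.glycemic_carb_g for f in foods)
    if carb == 0:
        return None
    return sum(f.glycemic_carb_g * f.gi for f in foods) / carb


def occasion_gl(foods: Sequence[ConsumedFood]) -> float:
    """Occasion glycemic load: Σ (glycemic carbohydrate × GI) / 100."""
    if not foods:
        raise ValueError("occasion_gl requires a non-empty food list")
    return sum(f.glycemic_carb_g * f.gi for f in foods) / 100.0


def daily_metrics(
    foods: Iterable[ConsumedFood], avgl_occasions: str = "all"
) -> DayMetrics:
    """All day-level metrics for one student-day from its consumed-food lines.

    ``avgl_occasions`` picks the AvGL divisor: ``"all"`` (every reported
    occasion; keeps AvGL × occasion count = DGL) or ``"carb_only"``.
    A day with zero glycemic carbohydrate has undefined DGI/AvGI (None) and
    DGL = 0; such students are excluded from GI models downstream.
    """
    foods = sorted(foods, key=lambda f: (f.occasion_order, f.occasion_id, f.food_id))
    if not foods:
        raise ValueError("daily_metrics requires at least one consumed food")
    student_ids = {f.student_id for f in foods}
    if len(student_ids) != 1:
        raise ValueError(f"daily_metrics got foods from several students: {student_ids}")

    by_occasion: dict[tuple[int, str], list[ConsumedFood]] = {}
    for f in foods:
        by_occasion.setdefault((f.occasion_order, f.occasion_id), []).append(f)

    occ = [
        OccasionMetrics(
            occasion_id=oid,
            occasion_order=order,
            gi=occasion_gi(lines),
            gl=occasion_gl(lines),
            carb_g=sum(l.glycemic_carb_g for l in lines),
        )
        for (order, oid), lines in by_occasion.items()
    ]

    total_carb = sum(o.carb_g for o in occ)
    dgl = sum(o.gl for o in occ)
    dgi = (
        sum(f.glycemic_carb_g * f.gi for f in foods) / total_carb if total_carb > 0 else None
    )
    carb_occ = [o for o in occ if o.carb_g > 0]
    av_gi = float(np.mean([o.gi for o in carb_occ])) if carb_occ else None
    gl_pool = occ if avgl_occasions == "all" else carb_occ
    av_gl = float(np.mean([o.gl for o in gl_pool])) if gl_pool else 0.0

    return DayMetrics(
        student_id=next(iter(student_ids)),
        dgi=dgi,
        dgl=dgl,
        av_gi=av_gi,
        av_gl=av_gl,
        n_occasions=len(occ),
        n_carb_occasions=len(carb_occ),
        total_glycemic_carb_g=total_carb,
    )


# ---------------------------------------------------------------------------
# vectorized pipeline over recall files


def resolve_recalls(
    recalls: pd.DataFrame, foods: Mapping[str, FoodItem] | pd.DataFrame
) -> pd.DataFrame:
    """Join recall lines to the resolved food table.

    Adds ``glycemic_carb_g`` (amount × available carbohydrate density) and
    ``gi`` per line, plus total carbohydrate/fiber/protein/lipid grams for
    energy accounting. Unknown food ids abort with the offending file rows
    named (header = line 1).
    """
    missing_cols = [c for c in RECALL_COLUMNS if c not in recalls.columns]
    if missing_cols:
        raise SchemaError(f"recall file missing columns {missing_cols}")
    table = foods if isinstance(foods, pd.DataFrame) else food_table_frame(foods)

    recalls = recalls.copy()
    recalls["amount_g"] = recalls["amount_g"].astype(float)
    if (recalls["amount_g"] <= 0).any():
        bad = recalls.index[recalls["amount_g"] <= 0] + 2
        raise SchemaError(f"non-positive amount_g at file line(s) {list(bad[:10])}")

    unknown = ~recalls["food_id"].isin(table.index)
    if unknown.any():
        lines = (recalls.index[unknown] + 2).tolist()
        ids = sorted(recalls.loc[unknown, "food_id"].unique())
        raise SchemaError(
            f"unknown food_id(s) {ids[:10]} at file line(s) {lines[:10]}"
        )

    merged = recalls.merge(
        table[["glycemic_carb_per_100g", "gi", "total_carb_g", "fiber_g", "protein_g", "lipid_g"]],
        left_on="food_id",
        right_index=True,
        how="left",
        sort=False,
    )
    scale = merged["amount_g"] / 100.0
    merged["glycemic_carb_g"] = scale * merged["glycemic_carb_per_100g"]
    for nutrient in ["total_carb_g", "fiber_g", "protein_g", "lipid_g"]:
        merged[nutrient] = scale * merged[nutrient]
    merged["occasion_order"] = merged["occasion_order"].astype(int)
    return merged.sort_values(
        ["student_id", "occasion_order", "occasion_id", "food_id"], kind="mergesort"
    ).reset_index(drop=True)


def compute_metrics(
    resolved: pd.DataFrame, avgl_occasions: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day- and occasion-level metric tables from resolved recall lines.

    Returns ``(day_df, occasion_df)``; ``day_df`` has one row per student
    ordered by student_id, ``occasion_df`` one row per eating occasion.
    """
    if avgl_occasions not in {"all", "carb_only"}:
        raise ValueError(f"avgl_occasions must be 'all' or 'carb_only', got {avgl_occasions!r}")
    df = resolved.copy()
    df["carb_gi"] = df["glycemic_carb_g"] * df["gi"]

    occ = (
        df.groupby(["student_id", "occasion_order", "occasion_id"], sort=True)
        .agg(carb_g=("glycemic_carb_g", "sum"), carb_gi=("carb_gi", "sum"))
        .reset_index()
    )
    occ["gl"] = occ["carb_gi"] / 100.0
    occ["gi"] = np.where(occ["carb_g"] > 0, occ["carb_gi"] / occ["carb_g"].replace(0, np.nan), np.nan)
    occ["_has_carb"] = (occ["carb_g"] > 0).astype(int)

    g = occ.groupby("student_id", sort=True)
    day = g.agg(
        total_glycemic_carb_g=("carb_g", "sum"),
        _carb_gi=("carb_gi", "sum"),
        n_occasions=("occasion_id", "size"),
        n_carb_occasions=("_has_carb", "sum"),
        av_gi=("gi", "mean"),  # mean skips NaN = zero-carb occasions
    )
    day["dgl"] = day["_carb_gi"] / 100.0
    day["dgi"] = np.where(
        day["total_glycemic_carb_g"] > 0,
        day["_carb_gi"] / day["total_glycemic_carb_g"].replace(0, np.nan),
        np.nan,
    )
    if avgl_occasions == "all":
        day["av_gl"] = g["gl"].mean()
    else:
        day["av_gl"] = occ[occ["carb_g"] > 0].groupby("student_id")["gl"].mean()
        day["av_gl"] = day["av_gl"].fillna(0.0)

    day = day.drop(columns="_carb_gi").reset_index()
    day = day[
        [
            "student_id",
            "dgi",
            "dgl",
            "av_gi",
            "av_gl",
            "n_occasions",
            "n_carb_occasions",
            "total_glycemic_carb_g",
        ]
    ]
    occasion_df = occ[["student_id", "occasion_id", "occasion_order", "gi", "gl", "carb_g"]]
    return day, occasion_df


def occasion_profile(
    occasion_df: pd.DataFrame, group: pd.Series | None = None
) -> pd.DataFrame:
    """Five-number boxplot summary of occasion GI per (occasion_order, group).

    Quartiles use linear interpolation; whiskers are the Tukey convention
    (most extreme observations within 1.5 IQR of the quartiles). Occasions
    without glycemic carbohydrate have no GI and are omitted. A group with no
    occasions at an order yields no row (absent, never zero).
    """
    df = occasion_df.copy()
    df["group"] = "all" if group is None else df["student_id"].map(group)
    df = df.dropna(subset=["gi", "group"])

    rows = []
    for (order, grp), sub in df.groupby(["occasion_order", "group"], sort=True):
        x = sub["gi"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
        iqr = q3 - q1
        in_fence = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
        rows.append(
            {
                "occasion_order": order,
                "group": grp,
                "q0": float(in_fence.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "q4": float(in_fence.max()),
                "n": len(x),
            }
        )
    return pd.DataFrame(rows, columns=["occasion_order", "group", "q0", "q1", "median", "q3", "q4", "n"])


def read_recalls(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"student_id": str, "occasion_id": str, "food_id": str}, comment="#")
    missing = [c for c in RECALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df
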