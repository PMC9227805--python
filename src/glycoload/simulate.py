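"""Seeded synthetic cohort: food table, 24 h-recall lines, students, design.

The generator emulates the structure of a national school-based adolescent
survey: students nested in schools (PSUs) nested in sampling strata, one
24 h recall per student with 3–6 eating occasions, lunch drawing
lower-GI staples (rice-and-beans regime) and between-meal snacks drawing
higher-GI sweets/drinks, and overweight/obese (OW) students reporting less
carbohydrate than normal-weight (NW) ones. Glycemic-control markers are
generated *conditional on the computed intake metrics*:

    marker = baseline(sex, OW) + covariate terms + Σ β·z(metric)
             + school effect N(0, cluster_sd²) + N(0, residual_sd²)

with z(metric) the survey-weighted z-score of the metric within the weight
stratum — the same standardization the analysis applies — so the generating
coefficients are directly the estimands of the fitted models. HOMA-IR is
derived from the generated glucose and insulin (glucose × insulin / 405),
never simulated independently.

Default group means sit in the regime of the published adolescent-survey
summaries the package targets (daily GI ≈ 59, NW-girl daily GL ≈ 165,
insulin ≈ 8.7/13.2 mU/L in NW/OW girls and 7.1/12.0 in boys, glucose
≈ 84–88 mg/dL, HbA1c ≈ 5.3–5.4%); see ``data/calibration_targets.csv``.
Everything is driven by one ``numpy.random.default_rng(seed)``, so identical
settings + seed give byte-identical output files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import clinical, food_gi, metrics
from .food_gi import FoodItem, GISource, ZeroClass

logger = logging.getLogger(__name__)

EffectKey = Tuple[str, str, str]  # (marker, metric, weight stratum)

#: default marker ~ z(metric) generating coefficients, per weight stratum
DEFAULT_EFFECTS: Dict[EffectKey, float] = {
    ("insulin", "av_gl", "NW"): 0.12,
    ("insulin", "av_gi", "OW"): 0.23,
    ("hba1c", "av_gl", "NW"): 0.006,
}


@dataclass
class SimulationSettings:
    """All knobs of the synthetic study; defaults ARE the emulated conditions."""

    n_strata: int = 4
    psus_per_stratum: int = 10
    students_per_psu: int = 50
    #: P(3), P(4), P(5), P(6) reported eating occasions; mean ≈ 4.45 matches
    #: the daily-GL / average-GL ratio of the targeted summaries
    occasion_count_probs: tuple = (0.15, 0.40, 0.30, 0.15)
    food_catalog_size: int = 50
    #: GI offset of the food-draw kernel at lunch (negative: staples) and at
    #: between-meal snacks (positive: sweets/sodas)
    lunch_gi_shift: float = -8.0
    snack_gi_shift: float = 8.0
    effects: Dict[EffectKey, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    cluster_sd: Dict[str, float] = field(
        default_factory=lambda: {"insulin": 0.4, "glucose": 0.8, "hba1c": 0.05}
    )
    residual_sd: Dict[str, float] = field(
        default_factory=lambda: {"insulin": 3.0, "glucose": 6.0, "hba1c": 0.30}
    )
    ow_prevalence: float = 0.25
    #: multiplicative reduction of reported carbohydrate for OW students
    #: (≈ 254/297, the OW/NW glycemic-carbohydrate ratio of the targets)
    ow_carb_reduction: float = 0.855
    female_prob: float = 0.60
    diabetes_prob: float = 0.033
    #: NW-girl mean daily glycemic carbohydrate, grams (≈ DGL 165 at DGI 59)
    base_day_carb_g: float = 280.0
    male_carb_factor: float = 1.18
    day_carb_cv: float = 0.30
    #: fraction of students re-interviewed for a second recall day
    second_day_fraction: float = 0.0
    seed: int = 0

    @property
    def n_students(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.students_per_psu

    def __post_init__(self):
        p = np.asarray(self.occasion_count_probs, dtype=float)
        if p.size != 4 or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("occasion_count_probs must be 4 non-negative values summing to 1")
        for d in (self.cluster_sd, self.residual_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")
        if self.food_catalog_size < 10:
            raise ValueError("food_catalog_size must be at least 10")
        if self.ow_prevalence == 0 and any(k[2] == "OW" for k in self.effects):
            warnings.warn("OW effects requested with ow_prevalence 0: the OW cell will be empty")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSettings":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "effects" in raw:
            raw["effects"] = {
                tuple(k.split("/")): float(v) for k, v in raw["effects"].items()
            }
        if "occasion_count_probs" in raw:
            raw["occasion_count_probs"] = tuple(raw["occasion_count_probs"])
        return cls(**raw)


@dataclass
class SimulatedCohort:
    students: pd.DataFrame
    recalls: pd.DataFrame
    food_table: Dict[str, FoodItem]
    day_metrics: pd.DataFrame
    occasion_metrics: pd.DataFrame
    recalls_day2: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# food catalog

# (class, GI low, GI high, carb/100g range, fiber/100g range, protein, lipid, share)
_CARB_CLASSES = [
    ("bean_stew", 26, 40, (12, 22), (4.0, 8.0), 6.0, 1.0, 0.08),
    ("rice_tuber", 48, 66, (22, 34), (1.0, 3.0), 3.0, 1.0, 0.18),
    ("bread_cereal", 66, 88, (45, 75), (2.0, 5.0), 9.0, 5.0, 0.18),
    ("pasta", 42, 56, (24, 32), (1.5, 3.0), 5.0, 2.0, 0.06),
    ("fruit", 38, 62, (10, 22), (1.5, 4.0), 1.0, 0.3, 0.12),
    ("dairy", 30, 46, (5, 13), (0.0, 0.0), 4.0, 3.5, 0.08),
    ("sweet", 62, 92, (55, 85), (0.5, 2.5), 4.0, 12.0, 0.14),
    ("sugary_drink", 56, 68, (8, 12), (0.0, 0.0), 0.2, 0.0, 0.08),
    ("salty_snack", 55, 76, (40, 62), (1.5, 3.5), 7.0, 20.0, 0.08),
]

# fixed zero-GI items (class rules): meats/sausage, diet soda, distilled spirit
_ZERO_ITEMS = [
    ("beef_grilled", "grilled beef", 0.0, 0.0, ZeroClass.MEAT_OFFAL_SAUSAGE, 26.0, 12.0),
    ("chicken_grilled", "grilled chicken", 0.0, 0.0, ZeroClass.MEAT_OFFAL_SAUSAGE, 27.0, 6.0),
    ("sausage_pork", "pork sausage", 1.0, 0.0, ZeroClass.MEAT_OFFAL_SAUSAGE, 16.0, 27.0),
    ("soda_diet", "diet carbonated beverage", 0.0, 0.0, ZeroClass.DIET_BEVERAGE, 0.0, 0.0),
    ("cachaca", "sugar-cane spirit", 0.0, 0.0, ZeroClass.DISTILLED_SPIRIT, 0.0, 0.0),
]


def generate_food_table(settings: SimulationSettings, rng: np.random.Generator) -> Dict[str, FoodItem]:
    """Random but internally consistent food catalog.

    GI values are drawn from a low/medium/high class mixture; a handful of
    items exercise the literature and similar-food provenance paths, and the
    fixed zero-class items exercise the GI-zero rules.
    """
    n_carb = settings.food_catalog_size - len(_ZERO_ITEMS) - 2  # 2 similar-food items appended below
    counts = np.maximum(1, np.round(np.array([c[-1] for c in _CARB_CLASSES]) * n_carb)).astype(int)
    while counts.sum() > n_carb:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_carb:
        counts[np.argmin(counts)] += 1

    foods: Dict[str, FoodItem] = {}
    for (cls, gi_lo, gi_hi, carb_rng, fib_rng, prot, lip, _), m in zip(_CARB_CLASSES, counts):
        for j in range(m):
            fid = f"{cls}_{j:02d}"
            foods[fid] = FoodItem(
                food_id=fid,
                name=f"{cls.replace('_', ' ')} {j + 1}",
                total_carb_g=round(float(rng.uniform(*carb_rng)), 1),
                fiber_g=round(float(rng.uniform(*fib_rng)), 1),
                gi=round(float(rng.uniform(gi_lo, gi_hi)), 1),
                gi_source=GISource.DIRECT,
                protein_g=round(prot * float(rng.uniform(0.7, 1.3)), 1),
                lipid_g=round(lip * float(rng.uniform(0.7, 1.3)), 1),
            )
    for fid, name, carb, fib, zcls, prot, lip in _ZERO_ITEMS:
        foods[fid] = FoodItem(
            food_id=fid,
            name=name,
            total_carb_g=carb,
            fiber_g=fib,
            zero_class=zcls,
            protein_g=prot,
            lipid_g=lip,
        )

    # provenance variety: one literature entry, two similar-food references
    carb_ids = [f for f in foods if foods[f].zero_class is None]
    lit = foods[carb_ids[0]]
    foods[lit.food_id] = replace(lit, gi_source=GISource.LITERATURE)
    for k, ref in zip((1, 2), (carb_ids[3], carb_ids[4])):
        fid = f"regional_dish_{k:02d}"
        base = foods[ref]
        foods[fid] = FoodItem(
            food_id=fid,
            name=f"regional dish {k}",
            total_carb_g=base.total_carb_g,
            fiber_g=base.fiber_g,
            similar_food_id=ref,
            protein_g=base.protein_g,
            lipid_g=base.lipid_g,
        )
    food_gi.validate_food_table(foods)
    return foods


# ---------------------------------------------------------------------------
# recall generation

_SCHEDULES = {
    3: ["breakfast", "lunch", "dinner"],
    4: ["breakfast", "lunch", "snack", "dinner"],
    5: ["breakfast", "snack", "lunch", "snack", "dinner"],
    6: ["breakfast", "snack", "lunch", "snack", "dinner", "snack"],
}
_CARB_SHARE = {"breakfast": 0.85, "lunch": 1.30, "dinner": 1.25, "snack": 0.55}
_GI_KERNEL_BASE = 61.5
_GI_KERNEL_WIDTH = 18.0


def _occasion_gi_center(occ_type: str, settings: SimulationSettings) -> float:
    if occ_type == "lunch":
        return _GI_KERNEL_BASE + settings.lunch_gi_shift
    if occ_type == "snack":
        return _GI_KERNEL_BASE + settings.snack_gi_shift
    return _GI_KERNEL_BASE


def _generate_recalls(
    settings: SimulationSettings,
    rng: np.random.Generator,
    students: pd.DataFrame,
    foods: Dict[str, FoodItem],
    day: int = 1,
) -> pd.DataFrame:
    resolved = food_gi.resolve_food_table(foods)
    carb_foods = sorted(
        (f for f in resolved.values() if f.glycemic_carb_per_100g >= 5 and f.zero_class is None),
        key=lambda f: f.food_id,
    )
    carb_ids = np.array([f.food_id for f in carb_foods])
    carb_gi = np.array([f.gi for f in carb_foods])
    carb_density = np.array([f.glycemic_carb_per_100g for f in carb_foods])
    meat_ids = [f.food_id for f in resolved.values() if f.zero_class == ZeroClass.MEAT_OFFAL_SAUSAGE]

    def kernel(center: float) -> np.ndarray:
        p = np.exp(-((carb_gi - center) ** 2) / (2 * _GI_KERNEL_WIDTH**2))
        return p / p.sum()

    n = len(students)
    occ_counts = rng.choice([3, 4, 5, 6], size=n, p=list(settings.occasion_count_probs))

    # occasion table
    sid = np.repeat(students["student_id"].to_numpy(), occ_counts)
    order = np.concatenate([np.arange(1, k + 1) for k in occ_counts])
    otype = np.concatenate([np.array(_SCHEDULES[k]) for k in occ_counts])
    occ = pd.DataFrame({"student_id": sid, "occasion_order": order, "occasion_type": otype})
    occ["occasion_id"] = occ["student_id"] + "-d" + str(day) + "-o" + occ["occasion_order"].astype(str)

    # per-student daily glycemic-carbohydrate target
    stu = students.set_index("student_id")
    target = settings.base_day_carb_g * np.where(
        stu["sex"].to_numpy() == "male", settings.male_carb_factor, 1.0
    )
    target = target * np.where(stu["bmi_z"].to_numpy() >= 1.0, settings.ow_carb_reduction, 1.0)
    cv = settings.day_carb_cv
    sigma = np.sqrt(np.log(1 + cv**2))
    target = target * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    occ["day_target"] = occ["student_id"].map(pd.Series(target, index=stu.index))

    # occasion carbohydrate shares
    occ["share_raw"] = occ["occasion_type"].map(_CARB_SHARE).to_numpy() * rng.lognormal(
        0, 0.25, len(occ)
    )
    occ["share"] = occ["share_raw"] / occ.groupby("student_id")["share_raw"].transform("sum")
    occ["occ_carb"] = occ["day_target"] * occ["share"]

    # a few snacks are diet-soda-only (zero glycemic carbohydrate occasions)
    is_snack = occ["occasion_type"].to_numpy() == "snack"
    soda_only = is_snack & (rng.random(len(occ)) < 0.03)

    # line counts: meals 2–4 foods, snacks 1–2
    n_lines = np.where(is_snack, rng.integers(1, 3, len(occ)), rng.integers(2, 5, len(occ)))
    n_lines = np.where(soda_only, 0, n_lines)

    line_occ = np.repeat(np.arange(len(occ)), n_lines)
    line_type = occ["occasion_type"].to_numpy()[line_occ]

    # food draw per occasion type (GI kernel centred per type)
    food_idx = np.empty(len(line_occ), dtype=int)
    for t in ["breakfast", "lunch", "dinner", "snack"]:
        mask = line_type == t
        if mask.any():
            food_idx[mask] = rng.choice(
                len(carb_ids), size=int(mask.sum()), p=kernel(_occasion_gi_center(t, settings))
            )

    # split occasion carbohydrate across its lines
    raw = rng.exponential(1.0, len(line_occ)) + 0.2
    line_df = pd.DataFrame({"occ_idx": line_occ, "raw": raw})
    line_df["share"] = line_df["raw"] / line_df.groupby("occ_idx")["raw"].transform("sum")
    line_carb = occ["occ_carb"].to_numpy()[line_occ] * line_df["share"].to_numpy()
    amount = np.clip(line_carb / carb_density[food_idx] * 100.0, 5.0, 1500.0)

    lines = pd.DataFrame(
        {
            "student_id": occ["student_id"].to_numpy()[line_occ],
            "occasion_id": occ["occasion_id"].to_numpy()[line_occ],
            "occasion_order": occ["occasion_order"].to_numpy()[line_occ],
            "food_id": carb_ids[food_idx],
            "amount_g": np.round(amount, 1),
        }
    )

    # meat at most lunches/dinners (protein/lipid, zero GI)
    is_main = occ["occasion_type"].isin(["lunch", "dinner"]).to_numpy()
    meat_mask = is_main & (rng.random(len(occ)) < 0.85)
    meat = occ.loc[meat_mask, ["student_id", "occasion_id", "occasion_order"]].copy()
    meat["food_id"] = rng.choice(meat_ids, size=len(meat))
    meat["amount_g"] = np.round(np.clip(rng.normal(130, 35, len(meat)), 40, 350), 1)

    # diet soda: the soda-only snacks plus 10% of ordinary snacks
    soda_mask = soda_only | (is_snack & (rng.random(len(occ)) < 0.10))
    soda = occ.loc[soda_mask, ["student_id", "occasion_id", "occasion_order"]].copy()
    soda["food_id"] = "soda_diet"
    soda["amount_g"] = 350.0

    recalls = pd.concat([lines, meat, soda], ignore_index=True)
    recalls = recalls.sort_values(
        ["student_id", "occasion_order", "occasion_id", "food_id"], kind="mergesort"
    ).reset_index(drop=True)
    return recalls[metrics.RECALL_COLUMNS]


# ---------------------------------------------------------------------------
# students and markers

_PA_EFFECT = {"inactive": 0.4, "insufficiently_active": 0.2, "active": 0.0}


def _generate_students(settings: SimulationSettings, rng: np.random.Generator) -> pd.DataFrame:
    from scipy import stats as sstats

    n = settings.n_students
    strata = [f"ST{h + 1}" for h in range(settings.n_strata)]
    psu_labels = [
        f"{s}-SCH{j + 1:02d}" for s in strata for j in range(settings.psus_per_stratum)
    ]
    psu = np.repeat(psu_labels, settings.students_per_psu)
    stratum = np.array([p.split("-")[0] for p in psu])
    sid = np.array([f"S{i + 1:06d}" for i in range(n)])

    female = rng.random(n) < settings.female_prob
    age = rng.uniform(12, 17, n)
    maturation = np.clip(np.round(1 + 0.75 * (age - 12) + rng.normal(0, 0.7, n)), 1, 5).astype(int)

    # physical activity minutes: a point mass at zero plus lognormal minutes
    p_zero = np.where(female, 0.26, 0.10)
    zero = rng.random(n) < p_zero
    minutes = np.where(
        female, rng.lognormal(np.log(240), 0.9, n), rng.lognormal(np.log(420), 0.9, n)
    )
    pa = np.round(np.where(zero, 0.0, minutes), 0)

    ow = rng.random(n) < settings.ow_prevalence
    bmi_nw = sstats.truncnorm.rvs(
        a=-np.inf, b=(1.0 - (-0.15)) / 0.75, loc=-0.15, scale=0.75, size=n, random_state=rng
    )
    bmi_ow = np.minimum(1.0 + rng.exponential(0.88, n), 4.0)
    bmi_z = np.round(np.where(ow, bmi_ow, bmi_nw), 3)

    weight = np.round(rng.lognormal(0, 0.3, n), 4)
    diabetes = (rng.random(n) < settings.diabetes_prob).astype(int)

    return pd.DataFrame(
        {
            "student_id": sid,
            "sex": np.where(female, "female", "male"),
            "age_years": np.round(age, 1),
            "maturation": maturation,
            "pa_min_week": pa,
            "bmi_z": bmi_z,
            "diabetes_self_report": diabetes,
            "stratum": stratum,
            "psu": psu,
            "weight": weight,
        }
    )


def _group_z(values: np.ndarray, weights: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Survey-weighted z-score within each weight stratum; NaN metric → 0 effect."""
    z = np.zeros_like(values, dtype=float)
    for g in np.unique(group):
        m = (group == g) & ~np.isnan(values)
        if m.sum() < 2:
            continue
        mean = np.average(values[m], weights=weights[m])
        sd = np.sqrt(np.average((values[m] - mean) ** 2, weights=weights[m]))
        if sd > 0:
            z[m] = (values[m] - mean) / sd
    return z


def _generate_markers(
    settings: SimulationSettings,
    rng: np.random.Generator,
    students: pd.DataFrame,
    day: pd.DataFrame,
) -> pd.DataFrame:
    df = students.merge(day, on="student_id", how="left", validate="one_to_one")
    n = len(df)
    female = (df["sex"] == "female").to_numpy().astype(float)
    ow = (df["bmi_z"].to_numpy() >= 1.0).astype(float)
    group = np.where(ow == 1.0, "OW", "NW")
    w = df["weight"].to_numpy(dtype=float)
    age_c = df["age_years"].to_numpy() - 14.5
    mat_c = df["maturation"].to_numpy() - 3.0
    pa_cat = clinical.pa_category(df["pa_min_week"].to_numpy())
    pa_eff = np.array([_PA_EFFECT.get(c, 0.0) for c in pa_cat])

    zcols = {m: _group_z(df[m].to_numpy(dtype=float), w, group) for m in ["dgi", "av_gi", "dgl", "av_gl"]}
    eff = {marker: np.zeros(n) for marker in ["insulin", "glucose", "hba1c"]}
    for (marker, metric, grp), b in settings.effects.items():
        eff[marker] += b * zcols[metric] * (group == grp)

    psu_codes, psu_idx = np.unique(df["psu"].to_numpy(), return_inverse=True)

    def cluster(name: str) -> np.ndarray:
        return rng.normal(0, settings.cluster_sd.get(name, 0.0), len(psu_codes))[psu_idx]

    insulin = (
        7.10
        + 1.61 * female
        + 4.94 * ow
        - 0.45 * female * ow
        + 0.10 * age_c
        + 0.15 * mat_c
        + pa_eff
        + eff["insulin"]
        + cluster("insulin")
        + rng.normal(0, settings.residual_sd["insulin"], n)
    )
    glucose = (
        86.80
        - 2.35 * female
        + 1.24 * ow
        - 0.43 * female * ow
        + 0.20 * age_c
        + eff["glucose"]
        + cluster("glucose")
        + rng.normal(0, settings.residual_sd["glucose"], n)
    )
    hba1c = (
        5.40
        - 0.07 * female
        + 0.02 * ow
        + 0.03 * female * ow
        + eff["hba1c"]
        + cluster("hba1c")
        + rng.normal(0, settings.residual_sd["hba1c"], n)
    )

    out = students.copy()
    out["glucose_mg_dl"] = np.round(np.clip(glucose, 55.0, 250.0), 2)
    out["insulin_mU_L"] = np.round(np.clip(insulin, 0.5, None), 2)
    out["hba1c_pct"] = np.round(np.clip(hba1c, 3.8, 8.5), 2)
    return out


def generate_cohort(settings: SimulationSettings, seed: Optional[int] = None) -> SimulatedCohort:
    """Full synthetic study: students + design, recalls, food table, metrics.

    Markers are generated conditional on the metrics computed by the real
    metrics pipeline, so estimation targets are unambiguous; HOMA-IR is a
    derivation (clinical module), not a simulation.
    """
    seed = settings.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    foods = generate_food_table(settings, rng)
    students = _generate_students(settings, rng)
    recalls = _generate_recalls(settings, rng, students, foods, day=1)

    resolved = metrics.resolve_recalls(recalls, foods)
    day, occ = metrics.compute_metrics(resolved)
    students = _generate_markers(settings, rng, students, day)

    recalls2 = None
    if settings.second_day_fraction > 0:
        sub_ids = students["student_id"].sample(
            frac=settings.second_day_fraction, random_state=int(rng.integers(2**31))
        )
        sub = students[students["student_id"].isin(sub_ids)]
        recalls2 = _generate_recalls(settings, rng, sub.reset_index(drop=True), foods, day=2)

    return SimulatedCohort(
        students=students,
        recalls=recalls,
        food_table=foods,
        day_metrics=day,
        occasion_metrics=occ,
        recalls_day2=recalls2,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the three delimited inputs the pipeline reads; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "food_table": outdir / "food_table.csv",
        "recalls": outdir / "recalls.csv",
        "students": outdir / "students.csv",
    }
    food_gi.write_food_table(cohort.food_table, paths["food_table"])
    cohort.recalls.to_csv(paths["recalls"], index=False)
    cohort.students.to_csv(paths["students"], index=False)
    if cohort.recalls_day2 is not None:
        paths["recalls_day2"] = outdir / "recalls_day2.csv"
        cohort.recalls_day2.to_csv(paths["recalls_day2"], index=False)
    return {k: str(v) for k, v in paths.items()}
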