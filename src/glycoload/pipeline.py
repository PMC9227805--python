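"""Orchestration: metrics run, descriptive tables, and the model grid.

Output files are headed by ``#`` comment lines carrying the package version,
the seed(s) used and a hash of the run configuration, so reruns with
identical inputs are byte-identical and self-describing. Energy is accounted
at the Atwater factors 4 kcal/g for carbohydrate and protein and 9 kcal/g
for lipid, the convention the targeted survey tables are internally
consistent with; percentages of energy therefore sum to 100 before rounding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, clinical, food_gi, metrics, survey
from .errors import SchemaError

logger = logging.getLogger(__name__)

KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "lipid": 9.0}


@dataclass
class RunConfig:
    """Paths and analysis flags for one reproducible run."""

    food_table: str
    recalls: str
    students: Optional[str] = None
    outdir: str = "results"
    #: "within_stratum" re-standardizes metrics inside each fitted weight
    #: stratum; "whole_sample" standardizes once before splitting
    standardization_scope: str = "within_stratum"
    #: AvGL divisor: "all" reported occasions or "carb_only"
    avgl_occasions: str = "all"
    lonely_psu: str = "error"
    covariates: Sequence[str] = field(default_factory=lambda: list(survey.DEFAULT_COVARIATES))
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.standardization_scope not in {"within_stratum", "whole_sample"}:
            raise ValueError(f"bad standardization_scope {self.standardization_scope!r}")
        if self.avgl_occasions not in {"all", "carb_only"}:
            raise ValueError(f"bad avgl_occasions {self.avgl_occasions!r}")
        if self.lonely_psu not in {"error", "merge"}:
            raise ValueError(f"bad lonely_psu {self.lonely_psu!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def check_paths(self) -> None:
        for p in [self.food_table, self.recalls, self.students]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def write_csv_with_meta(df: pd.DataFrame, path, config: RunConfig, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# glycoload {__version__}", f"# config_sha1: {config.digest()}"]
    if config.seed is not None:
        header.append(f"# seed: {config.seed}")
    header += [f"# {k}: {v}" for k, v in meta.items()]
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def percent_energy(carb_g: float, protein_g: float, lipid_g: float) -> dict:
    """Percent of energy from each macronutrient at 4/4/9 kcal/g.

    Computed from group means exactly as survey tables print them: energy is
    the Atwater sum of the three mean intakes, each share rounded to the
    nearest integer percent.
    """
    energy = (
        KCAL_PER_G["carb"] * carb_g + KCAL_PER_G["protein"] * protein_g + KCAL_PER_G["lipid"] * lipid_g
    )
    return {
        "energy_kcal": energy,
        "carb_pct": round(100.0 * KCAL_PER_G["carb"] * carb_g / energy),
        "protein_pct": round(100.0 * KCAL_PER_G["protein"] * protein_g / energy),
        "lipid_pct": round(100.0 * KCAL_PER_G["lipid"] * lipid_g / energy),
    }


def percent_energy_from_reported(energy_kcal, carb_g, protein_g, lipid_g) -> dict:
    """Percent of energy against an independently reported mean energy."""
    return {
        "energy_kcal": energy_kcal,
        "carb_pct": round(100.0 * KCAL_PER_G["carb"] * carb_g / energy_kcal),
        "protein_pct": round(100.0 * KCAL_PER_G["protein"] * protein_g / energy_kcal),
        "lipid_pct": round(100.0 * KCAL_PER_G["lipid"] * lipid_g / energy_kcal),
    }


def run_metrics(config: RunConfig) -> dict:
    """Compute day metrics and occasion profiles from the configured inputs.

    Writes ``metrics.csv`` (one row per student, ordered by student_id) and
    ``occasion_profiles.csv`` (five-number occasion-GI summaries, grouped by
    weight stratum when a students file is configured). Unresolved GIs and
    schema violations abort with line-numbered messages.
    """
    config.check_paths()
    foods = food_gi.load_food_table(config.food_table)
    recalls = metrics.read_recalls(config.recalls)
    resolved = metrics.resolve_recalls(recalls, foods)
    day, occ = metrics.compute_metrics(resolved, avgl_occasions=config.avgl_occasions)

    group = None
    if config.students:
        students = clinical.prepare_students(clinical.read_students(config.students))
        group = students.set_index("student_id")["weight_stratum"]
    profiles = metrics.occasion_profile(occ, group)

    outdir = Path(config.outdir)
    write_csv_with_meta(day, outdir / "metrics.csv", config, rows=len(day))
    write_csv_with_meta(profiles, outdir / "occasion_profiles.csv", config, rows=len(profiles))
    zero_days = int((day["total_glycemic_carb_g"] <= 0).sum())
    if zero_days:
        logger.warning("%d student-day(s) with zero glycemic carbohydrate flagged", zero_days)
    return {
        "day_metrics": day,
        "occasion_metrics": occ,
        "occasion_profiles": profiles,
        "resolved_recalls": resolved,
    }


def _nutrient_totals(resolved: pd.DataFrame) -> pd.DataFrame:
    """Per-student daily energy and macronutrient grams from resolved lines."""
    tot = resolved.groupby("student_id", sort=True)[
        ["total_carb_g", "fiber_g", "protein_g", "lipid_g", "glycemic_carb_g"]
    ].sum()
    tot["energy_kcal"] = (
        KCAL_PER_G["carb"] * tot["total_carb_g"]
        + KCAL_PER_G["protein"] * tot["protein_g"]
        + KCAL_PER_G["lipid"] * tot["lipid_g"]
    )
    return tot.reset_index()


DESCRIPTIVE_VARS = [
    "age_years",
    "dgi",
    "av_gi",
    "dgl",
    "av_gl",
    "glucose_mg_dl",
    "hba1c",
    "insulin",
    "homa_ir",
]


def descriptive_table(df: pd.DataFrame, variables=DESCRIPTIVE_VARS, by=("sex", "weight_stratum"), lonely_psu="error") -> pd.DataFrame:
    """Survey-weighted means with 95% CIs by sex × weight stratum."""
    rows = []
    for keys, sub in df.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for var in variables:
            if var not in sub.columns:
                continue
            est = survey.survey_mean(
                sub[var], sub["stratum"], sub["psu"], sub["weight"], lonely_psu=lonely_psu
            )
            rows.append({**dict(zip(by, keys)), "variable": var, **est})
    return pd.DataFrame(rows)


def energy_table(resolved: pd.DataFrame, students: pd.DataFrame, lonely_psu="error") -> pd.DataFrame:
    """Energy/macronutrient survey means and % of energy by weight stratum."""
    tot = _nutrient_totals(resolved).merge(
        students[["student_id", "stratum", "psu", "weight", "weight_stratum"]],
        on="student_id",
        how="inner",
    )
    rows = []
    for group, sub in tot.groupby("weight_stratum", sort=True):
        means = {
            var: survey.survey_mean(sub[var], sub["stratum"], sub["psu"], sub["weight"], lonely_psu=lonely_psu)
            for var in ["energy_kcal", "total_carb_g", "glycemic_carb_g", "fiber_g", "protein_g", "lipid_g"]
        }
        pct = percent_energy(
            means["total_carb_g"]["mean"], means["protein_g"]["mean"], means["lipid_g"]["mean"]
        )
        for var, est in means.items():
            rows.append(
                {
                    "weight_stratum": group,
                    "variable": var,
                    "mean": est["mean"],
                    "ci_low": est["ci_low"],
                    "ci_high": est["ci_high"],
                    "n": est["n"],
                    "pct_energy": {
                        "total_carb_g": pct["carb_pct"],
                        "protein_g": pct["protein_pct"],
                        "lipid_g": pct["lipid_pct"],
                    }.get(var, np.nan),
                }
            )
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict:
    """Full association analysis: filters, descriptives, and the model grid.

    Emits ``regression_results.csv`` (tidy 24-cell grid), a formatted
    ``coefficient_grid.txt``, ``descriptives.csv`` (marker/metric means with
    95% CIs by sex × weight stratum), ``energy_table.csv`` and
    ``exclusions.csv``. Join losses between students and metrics are logged,
    never silent.
    """
    config.check_paths()
    if not config.students:
        raise SchemaError("run_analysis requires a students file")
    met = run_metrics(config)
    students = clinical.prepare_students(clinical.read_students(config.students))
    retained, excl_log = clinical.exclusion_filter(students)

    day = met["day_metrics"]
    joined_ids = set(retained["student_id"]) & set(day["student_id"])
    lost_students = len(retained) - len(joined_ids)
    lost_days = len(day) - len(joined_ids)
    if lost_students or lost_days:
        logger.warning(
            "join losses: %d students without metrics, %d metric rows without student",
            lost_students,
            lost_days,
        )

    results = survey.fit_model_grid(
        retained,
        day,
        covariates=config.covariates,
        standardization_scope=config.standardization_scope,
        lonely_psu=config.lonely_psu,
    )

    analysis_df = retained.merge(day, on="student_id", how="inner")
    desc = descriptive_table(analysis_df, lonely_psu=config.lonely_psu)
    energy = energy_table(
        met["resolved_recalls"], retained.merge(day[["student_id"]], on="student_id"), lonely_psu=config.lonely_psu
    )

    outdir = Path(config.outdir)
    write_csv_with_meta(results, outdir / "regression_results.csv", config, models=len(results))
    write_csv_with_meta(desc, outdir / "descriptives.csv", config)
    write_csv_with_meta(energy, outdir / "energy_table.csv", config)
    write_csv_with_meta(excl_log, outdir / "exclusions.csv", config)
    (outdir / "coefficient_grid.txt").write_text(format_coefficient_grid(results))
    return {
        "results": results,
        "descriptives": desc,
        "energy": energy,
        "exclusions": excl_log,
        **met,
    }


def format_coefficient_grid(results: pd.DataFrame) -> str:
    """Render the marker × metric coefficient grid as aligned text, one block
    per weight stratum (β and p per cell)."""
    metric_label = {"dgi": "Daily GI", "av_gi": "Average GI", "dgl": "Daily GL", "av_gl": "Average GL"}
    marker_label = {"hba1c": "Glycosylated Hemoglobin", "insulin": "Insulin", "homa_ir": "HOMA-IR"}
    group_label = {"NW": "Normal weight", "OW": "Overweight/Obese"}
    lines = []
    for group in ["NW", "OW"]:
        sub = results[results["stratum_group"] == group]
        if sub.empty:
            lines.append(f"{group_label[group]}: no fitted models (empty stratum)\n")
            continue
        lines.append(group_label[group])
        head = f"{'':<12}" + "".join(f"{marker_label[m]:>26}" for m in ["hba1c", "insulin", "homa_ir"])
        lines.append(head)
        lines.append(f"{'':<12}" + f"{'β':>16}{'p':>10}" * 3)
        for metric in ["dgi", "av_gi", "dgl", "av_gl"]:
            row = f"{metric_label[metric]:<12}"
            for marker in ["hba1c", "insulin", "homa_ir"]:
                cell = sub[(sub["marker"] == marker) & (sub["metric"] == metric)]
                if cell.empty:
                    row += f"{'—':>16}{'—':>10}"
                else:
                    beta, p = float(cell["beta"].iloc[0]), float(cell["p_value"].iloc[0])
                    ptxt = "<0.0001" if p < 1e-4 else f"{p:.4f}"
                    row += f"{beta:>16.3f}{ptxt:>10}"
            lines.append(row)
        lines.append("")
    return "\n".join(lines) + "\n"


def plot_occasion_profile(profiles: pd.DataFrame, path) -> None:
    """Optional boxplot rendering of the occasion-GI summaries (decoration)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    groups = sorted(profiles["group"].unique())
    width = 0.8 / max(len(groups), 1)
    for gi, group in enumerate(groups):
        sub = profiles[profiles["group"] == group]
        pos = sub["occasion_order"] + (gi - (len(groups) - 1) / 2) * width
        stats = [
            {
                "med": r["median"],
                "q1": r["q1"],
                "q3": r["q3"],
                "whislo": r["q0"],
                "whishi": r["q4"],
                "label": str(int(r["occasion_order"])),
            }
            for _, r in sub.iterrows()
        ]
        ax.bxp(stats, positions=pos, widths=width * 0.9, showfliers=False)
    ax.set_xlabel("eating occasion (order within day)")
    ax.set_ylabel("occasion GI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
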