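"""Bundled demonstration data.

``calibration_targets`` holds the published adolescent-survey group means
(dietary metrics, glycemic-control markers by sex × weight status, and
energy/macronutrient intakes by weight status) that the synthetic-cohort
generator is calibrated against; the original cohort is restricted, so these
summaries are the only real-data anchor the package ships.

``demo_food_table`` is a ~50-item demonstration composition/GI table (it is
not the University of Sydney database); ``demo_recalls``/``demo_students``
are a tiny synthetic 10-student fixture for the worked examples.
"""

from importlib import resources
from pathlib import Path

import pandas as pd


def _data_path(name: str) -> Path:
    return Path(resources.files("glycoload.data") / name)


def demo_food_table_path() -> Path:
    return _data_path("demo_food_table.csv")


def demo_recalls_path() -> Path:
    return _data_path("demo_recalls.csv")


def demo_students_path() -> Path:
    return _data_path("demo_students.csv")


def calibration_targets() -> pd.DataFrame:
    """Long table ``variable,sex,weight_status,value`` of target group means."""
    return pd.read_csv(_data_path("calibration_targets.csv"))


def calibration_value(variable: str, weight_status: str, sex: str = "all") -> float:
    df = calibration_targets()
    row = df[
        (df["variable"] == variable)
        & (df["weight_status"] == weight_status)
        & (df["sex"] == sex)
    ]
    if row.empty:
        raise KeyError(f"no calibration target for {variable}/{sex}/{weight_status}")
    return float(row["value"].iloc[0])
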