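import numpy as np
import pandas as pd
import pytest

from glycoload import datasets, food_gi
from glycoload.simulate import SimulationSettings, generate_cohort


@pytest.fixture(scope="session")
def demo_foods():
    return food_gi.load_food_table(datasets.demo_food_table_path())


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated study reused across tests (4 strata × 6 schools × 30)."""
    settings = SimulationSettings(n_strata=4, psus_per_stratum=6, students_per_psu=30)
    return generate_cohort(settings, seed=3)


def random_day_lines(rng: np.random.Generator, student_id: str = "S1") -> pd.DataFrame:
    """One random student-day of recall-like resolved lines (≤5 occasions, ≤4 foods)."""
    n_occ = rng.integers(1, 6)
    rows = []
    for o in range(1, n_occ + 1):
        for j in range(rng.integers(1, 5)):
            amount = rng.uniform(10, 500)
            carb_frac = rng.uniform(0, 0.9) if rng.random() > 0.1 else 0.0
            rows.append(
                {
                    "student_id": student_id,
                    "occasion_id": f"{student_id}-o{o}",
                    "occasion_order": o,
                    "food_id": f"f{o}_{j}",
                    "amount_g": amount,
                    "glycemic_carb_g": amount * carb_frac,
                    "gi": rng.uniform(0, 120),
                }
            )
    return pd.DataFrame(rows)
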