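#!/usr/bin/env python
"""Generate the seeded synthetic study the downstream stages analyse.

Writes food_table.csv, recalls.csv and students.csv under
results/simulated/ and prints the cohort's basic accounting (students,
schools, recall lines, weight-status and diabetes frequencies).
"""

import numpy as np

from glycoload.simulate import SimulationSettings, generate_cohort, write_cohort

SEED = 42

settings = SimulationSettings()
cohort = generate_cohort(settings, seed=SEED)
paths = write_cohort(cohort, "results/simulated")

st = cohort.students
ow = (st["bmi_z"] >= 1).mean()
print(f"seed {SEED}: {len(st)} students in {st['psu'].nunique()} schools / "
      f"{st['stratum'].nunique()} strata; {len(cohort.recalls)} recall lines")
print(f"female {100 * (st['sex'] == 'female').mean():.1f}%, "
      f"overweight/obese {100 * ow:.1f}%, "
      f"self-reported diabetes {100 * st['diabetes_self_report'].mean():.1f}%")
print(f"occasions/day: mean {cohort.day_metrics['n_occasions'].mean():.2f} "
      f"(range {cohort.day_metrics['n_occasions'].min()}–{cohort.day_metrics['n_occasions'].max()})")
for k, v in paths.items():
    print(f"  {k}: {v}")
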