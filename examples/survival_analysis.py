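"""Relate brain activity to progression-free survival.

Simulates progression times whose hazard rises with a known factor per
standard deviation of activity, then fits a Cox proportional-hazards
model with age and WHO grade as covariates and recovers that factor.
A Kaplan-Meier median split of activity illustrates the same effect
nonparametrically.
"""

import numpy as np
import pandas as pd

from periglioma import cox_ph, km_median_split
from periglioma.cohort import simulate_progression

rng = np.random.default_rng(5)
n = 300
subjects = pd.DataFrame({
    "subject_id": [f"P{i:03d}" for i in range(n)],
    "age": rng.normal(44, 14, n).clip(18, 85),
    "who_grade": rng.choice([2, 3, 4], size=n, p=[0.58, 0.18, 0.24])})
activity = rng.normal(size=n)           # z-scored global activity

true_hr = 2.0
prog = simulate_progression(subjects, activity, true_hr,
                            censor_rate=0.4, rng=rng)

df = pd.DataFrame({"time_weeks": prog["time_weeks"],
                   "event": prog["event"],
                   "activity_z": activity,
                   "age": subjects["age"],
                   "grade": subjects["who_grade"].astype(float)})
estimates = cox_ph(df, ["activity_z", "age", "grade"])
he = estimates["activity_z"]
print(f"true hazard ratio per SD of activity: {true_hr:.2f}")
print(f"Cox estimate: HR={he.hazard_ratio:.2f} "
      f"(95% CI {he.ci_95[0]:.2f}-{he.ci_95[1]:.2f}, p={he.p_value:.2g}, "
      f"{he.n_events} events)")

curves, threshold = km_median_split(df, activity)
week = 52.0
for label, curve in curves.items():
    idx = curve.index[curve.index <= week]
    s = float(curve.loc[idx[-1]].iloc[0]) if len(idx) else 1.0
    print(f"{label}-activity group: {s:.0%} progression-free at one year")
print("higher activity carrying a shorter progression-free interval is "
      "the modelled direction")
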