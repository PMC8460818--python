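"""Classify tumor-volume trajectories as stable or increasing.

The rule compares the two MRI scans surrounding the MEG: changes below
1 ml are stable, above 5 ml increasing, and changes in between are
resolved by the next follow-up scan (pseudoprogression - a transient
rise that settles - counts as stable).
"""

import numpy as np

from periglioma import VolumeSeries, classify_growth, volume_change

cases = {
    "slow drift":        ([-100, -20, 45, 130], [12.0, 12.4, 12.9, 12.6]),
    "clear growth":      ([-100, -20, 45, 130], [12.0, 13.0, 21.0, 25.0]),
    "confirmed growth":  ([-100, -20, 45, 130], [12.0, 13.0, 16.0, 19.0]),
    "pseudoprogression": ([-100, -20, 45, 130], [12.0, 13.0, 16.0, 13.5]),
    "from zero":         ([-100, -20, 45, 130], [0.0, 0.0, 7.5, 9.0]),
}

for name, (days, vols) in cases.items():
    series = VolumeSeries(name, np.array(days), np.array(vols), meg_day=0)
    change = volume_change(series)
    label = classify_growth(series, change)
    pct = "undefined" if change.delta_pct is None \
        else f"{change.delta_pct:+.0f}%"
    print(f"{name:18s} delta {change.delta_ml:+5.1f} ml ({pct:>9s}) "
          f"-> {label.label:10s} [{label.rationale}]")

print("\n'rationale' names the rule branch, so boundary cases "
      "(1-5 ml changes resolved by the following MRI) stay auditable; "
      "percent change is undefined when the pre-MEG volume is 0 ml")
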