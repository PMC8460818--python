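"""Tumor-volume change around the MEG and the growth classifier.

The change score is the difference between the last MRI volume before
the MEG and the first MRI volume after it (absolute ml, and percent of
the pre volume when that is nonzero).  Patients are classified as

* ``stable``      if the signed change is < 1 ml,
* ``increasing``  if the change is > 5 ml,
* otherwise (changes in [1, 5] ml) the next follow-up scan decides:
  further growth beyond a configurable margin (default: any strictly
  positive change) means ``increasing``, a flat or shrinking follow-up
  means ``stable`` (the pseudoprogression pattern), and a missing
  follow-up defaults to ``stable`` with an explicit rationale code so
  the ambiguity stays auditable.

Shrinking tumors fall under the signed "< 1 ml" branch and are stable.
Volumes are taken as given in ml; no image segmentation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "VolumeSeries",
    "VolumeChange",
    "GrowthClass",
    "MissingScanError",
    "select_surrounding_scans",
    "compute_change",
    "volume_change",
    "classify_growth",
]

#: Follow-up window for the lookahead branch, days after the MEG.
LOOKAHEAD_WINDOW_DAYS = 365


class MissingScanError(ValueError):
    """A patient lacks a scan on one side of the MEG (excluded subject)."""

    def __init__(self, subject_id: str, side: str):
        self.subject_id = subject_id
        self.side = side
        super().__init__(
            f"subject {subject_id}: no {side}-MEG scan available")


@dataclass
class VolumeSeries:
    """Dated tumor volumes (ml) around a MEG recording.

    ``scan_days`` and ``meg_day`` are integers in days relative to
    surgery; scan days must be strictly increasing and volumes >= 0.
    """

    subject_id: str
    scan_days: np.ndarray
    volumes: np.ndarray
    meg_day: int

    def __post_init__(self):
        self.scan_days = np.asarray(self.scan_days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.scan_days.shape != self.volumes.shape:
            raise ValueError("scan_days and volumes must align")
        if np.any(np.diff(self.scan_days) <= 0):
            raise ValueError("scan days must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be >= 0 ml")

    @property
    def n_scans(self) -> int:
        return len(self.scan_days)


@dataclass
class VolumeChange:
    """Volume difference between the two scans surrounding the MEG."""

    subject_id: str
    pre_volume: float
    post_volume: float
    delta_ml: float
    delta_pct: Optional[float]     # None when pre_volume == 0
    pre_scan_day: int
    post_scan_day: int
    meg_day: int


@dataclass
class GrowthClass:
    """Stable/increasing label plus the rule branch that produced it."""

    label: str        # 'stable' | 'increasing'
    rationale: str    # below_1 | above_5 | lookahead_growth |
    #                   lookahead_stable | lookahead_missing

    def __post_init__(self):
        consistent = {
            "below_1": "stable",
            "above_5": "increasing",
            "lookahead_growth": "increasing",
            "lookahead_stable": "stable",
            "lookahead_missing": "stable",
        }
        if consistent.get(self.rationale) != self.label:
            raise ValueError(
                f"label {self.label!r} inconsistent with rationale "
                f"{self.rationale!r}")


def select_surrounding_scans(series: VolumeSeries
                             ) -> Tuple[Tuple[int, float], Tuple[int, float]]:
    """The latest scan on/before the MEG day and the earliest one after.

    A scan acquired on the MEG day counts as the *pre* scan (follow-up
    intervals of zero days occur in routine practice).  A missing side
    raises :class:`MissingScanError`, mirroring the exclusion of
    patients without MRI follow-up.
    """
    days, vols = series.scan_days, series.volumes
    before = np.flatnonzero(days <= series.meg_day)
    after = np.flatnonzero(days > series.meg_day)
    if len(before) == 0:
        raise MissingScanError(series.subject_id, "pre")
    if len(after) == 0:
        raise MissingScanError(series.subject_id, "post")
    i, j = before[-1], after[0]
    return (int(days[i]), float(vols[i])), (int(days[j]), float(vols[j]))


def compute_change(pre: Tuple[int, float], post: Tuple[int, float],
                   subject_id: str = "", meg_day: int = 0) -> VolumeChange:
    """Absolute (ml) and percent change between two (day, volume) scans.

    Percent change is undefined (``None``) when the pre volume is 0 ml.
    """
    (pre_day, pre_vol), (post_day, post_vol) = pre, post
    if pre_vol < 0 or post_vol < 0:
        raise ValueError("volumes must be >= 0")
    delta = post_vol - pre_vol
    pct = 100.0 * delta / pre_vol if pre_vol > 0 else None
    return VolumeChange(subject_id=subject_id, pre_volume=pre_vol,
                        post_volume=post_vol, delta_ml=delta, delta_pct=pct,
                        pre_scan_day=pre_day, post_scan_day=post_day,
                        meg_day=meg_day)


def volume_change(series: VolumeSeries) -> VolumeChange:
    """Convenience: select the surrounding scans and compute the change."""
    pre, post = select_surrounding_scans(series)
    return compute_change(pre, post, subject_id=series.subject_id,
                          meg_day=series.meg_day)


def classify_growth(series: VolumeSeries,
                    change: Optional[VolumeChange] = None,
                    growth_margin: float = 0.0,
                    lookahead_days: int = LOOKAHEAD_WINDOW_DAYS
                    ) -> GrowthClass:
    """Apply the stable/increasing rule with next-scan lookahead.

    delta < 1 ml -> stable; delta > 5 ml -> increasing; deltas in
    [1, 5] ml (boundaries included: the lookahead uses strictly more
    information than either threshold) are increasing iff the next scan
    within ``lookahead_days`` after the MEG shows growth beyond
    ``growth_margin`` ml, stable otherwise or when no such scan exists.
    """
    if change is None:
        change = volume_change(series)
    delta = change.delta_ml
    if delta < 1.0:
        return GrowthClass("stable", "below_1")
    if delta > 5.0:
        return GrowthClass("increasing", "above_5")
    days, vols = series.scan_days, series.volumes
    horizon = series.meg_day + lookahead_days
    nxt = np.flatnonzero((days > change.post_scan_day) & (days <= horizon))
    if len(nxt) == 0:
        return GrowthClass("stable", "lookahead_missing")
    if float(vols[nxt[0]]) - change.post_volume > growth_margin:
        return GrowthClass("increasing", "lookahead_growth")
    return GrowthClass("stable", "lookahead_stable")
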