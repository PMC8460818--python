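"""Spatial levels of analysis: peritumoral sets, contralateral
homologues, normalization, distance subgroups and hemisphere averages.

Peritumoral activity is summarized over ten locations within 3 cm of
the tumor rim in the tumor hemisphere; each location is paired with its
mirror-image homologue in the opposite hemisphere, and the peritumoral
summary is normalized by the contralateral one (element-wise ratio of
broadband power, offset and slope) to cancel pre-existing regional
differences in activity.  Patients are additionally split into long
(> 75th percentile) and short (< 25th percentile) subgroups of the mean
peritumoral-contralateral Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Sequence

import numpy as np

from .atlas import RegionAtlas, mirror_point
from .spectral import ActivitySummary

__all__ = [
    "PeritumoralSelection",
    "HomologuePairing",
    "select_peritumoral_regions",
    "map_contralateral_homologues",
    "mean_euclidean_distance",
    "normalize_by_contralateral",
    "distance_subgroups",
    "summarize_hemispheres",
]


@dataclass
class PeritumoralSelection:
    """Ten tumor-hemisphere locations within reach of the tumor rim."""

    subject_id: str
    region_indices: np.ndarray     # (n,) atlas indices, tumor hemisphere
    coordinates: np.ndarray        # (n, 3) mm
    tumor_centroid: np.ndarray     # (3,) mm
    tumor_radius_mm: float         # rim = sphere of this radius
    max_distance: float = 30.0

    def __post_init__(self):
        self.region_indices = np.asarray(self.region_indices, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        rim = np.linalg.norm(self.coordinates - self.tumor_centroid,
                             axis=1) - self.tumor_radius_mm
        # tolerance covers text round-trips of coordinates
        if np.any(rim > self.max_distance + 1e-5):
            raise ValueError("peritumoral location beyond the rim distance "
                             "constraint")

    @property
    def n_locations(self) -> int:
        return len(self.region_indices)


@dataclass
class HomologuePairing:
    """One-to-one pairing of peritumoral and contralateral locations."""

    subject_id: str
    peritumoral_indices: np.ndarray
    contralateral_indices: np.ndarray
    peritumoral_coords: np.ndarray
    contralateral_coords: np.ndarray

    def __post_init__(self):
        if len(self.peritumoral_indices) != len(self.contralateral_indices):
            raise ValueError("pairing must be one-to-one")
        if len(np.unique(self.contralateral_indices)) != \
                len(self.contralateral_indices):
            raise ValueError("contralateral locations must be distinct")


def select_peritumoral_regions(atlas: RegionAtlas, hemisphere: str,
                               tumor_radius_mm: float,
                               rng: np.random.Generator,
                               subject_id: str = "",
                               n: int = 10,
                               max_distance: float = 30.0
                               ) -> PeritumoralSelection:
    """Designate ``n`` peritumoral regions for a synthetic tumor.

    A tumor centroid is placed at a randomly chosen region centroid of
    the tumor hemisphere (jittered by a few mm); the ``n`` regions of
    that hemisphere nearest to the tumor *rim* (centroid distance minus
    tumor radius) and within ``max_distance`` of it are selected.
    Candidate centroids are tried in random order until one offers
    enough in-range regions; as a last resort the tumor radius is
    enlarged minimally so the constraint can be met, which is recorded
    in the returned selection.
    """
    hemi_idx = atlas.hemisphere_indices(hemisphere)
    if len(hemi_idx) < n:
        raise ValueError(f"hemisphere has {len(hemi_idx)} regions, "
                         f"{n} peritumoral locations requested")
    order = rng.permutation(len(hemi_idx))
    best = None
    for cand in order:
        centroid = atlas.centroids[hemi_idx[cand]] + rng.normal(0.0, 3.0, 3)
        centroid[0] = np.sign(atlas.centroids[hemi_idx[cand], 0]) * \
            max(abs(centroid[0]), 5.0)  # stay off the midline
        dist = np.linalg.norm(atlas.centroids[hemi_idx] - centroid, axis=1)
        rim = dist - tumor_radius_mm
        in_range = np.sum(rim <= max_distance)
        if best is None or in_range > best[0]:
            best = (in_range, centroid, rim)
        if in_range >= n:
            break
    in_range, centroid, rim = best
    radius = tumor_radius_mm
    if in_range < n:
        # minimal radius enlargement making n regions reachable
        radius = tumor_radius_mm + (np.sort(rim)[n - 1] - max_distance)
        rim = rim - (radius - tumor_radius_mm)
    chosen = hemi_idx[np.argsort(rim, kind="stable")[:n]]
    return PeritumoralSelection(
        subject_id=subject_id, region_indices=np.sort(chosen),
        coordinates=atlas.centroids[np.sort(chosen)],
        tumor_centroid=centroid, tumor_radius_mm=float(radius),
        max_distance=max_distance)


def map_contralateral_homologues(selection: PeritumoralSelection,
                                 atlas: RegionAtlas,
                                 midline_self_map: bool = False
                                 ) -> HomologuePairing:
    """Mirror each peritumoral location about x = 0 and snap it to its
    homologue region in the opposite hemisphere.

    Locations exactly on the midline (x = 0) have no mirror image; by
    default they raise, or self-map when ``midline_self_map`` is set.
    """
    peri = selection.region_indices
    contra = []
    for idx in peri:
        x = atlas.centroids[idx, 0]
        if x == 0.0:
            if midline_self_map:
                contra.append(idx)
                continue
            raise ValueError(
                f"region {atlas.region_ids[idx]} lies on the midline and "
                "has no contralateral homologue")
        contra.append(atlas.homologue_of(idx))
    contra = np.asarray(contra, dtype=int)
    mirrored = np.array([mirror_point(c) for c in selection.coordinates])
    return HomologuePairing(
        subject_id=selection.subject_id,
        peritumoral_indices=peri, contralateral_indices=contra,
        peritumoral_coords=selection.coordinates,
        contralateral_coords=mirrored)


def mean_euclidean_distance(pairing: HomologuePairing) -> float:
    """Mean straight-line distance over the homologue pairs (mm)."""
    if len(pairing.peritumoral_indices) == 0:
        raise ValueError("pairing is empty")
    d = np.linalg.norm(pairing.peritumoral_coords
                       - pairing.contralateral_coords, axis=1)
    return float(d.mean())


def normalize_by_contralateral(peritumoral: ActivitySummary,
                               contralateral: ActivitySummary
                               ) -> ActivitySummary:
    """Element-wise peritumoral / contralateral ratio of the measures.

    The broadband-power ratio requires a strictly positive contralateral
    power.  Offsets and slopes are on a log10 / exponent scale and may
    legitimately be negative; when the sign differs between sides the
    ratio is hard to interpret, so the output carries a flag.
    """
    if contralateral.broadband_power <= 0:
        raise ValueError("contralateral broadband power must be positive "
                         "for ratio normalization")
    if contralateral.offset == 0 or contralateral.slope == 0:
        raise ValueError("contralateral offset/slope of exactly zero "
                         "cannot normalize a ratio")
    flags = []
    for name in ("offset", "slope"):
        if getattr(peritumoral, name) * getattr(contralateral, name) < 0:
            flags.append(f"sign_mismatch_{name}")
    return replace(
        peritumoral,
        level="normalized",
        broadband_power=peritumoral.broadband_power
        / contralateral.broadband_power,
        offset=peritumoral.offset / contralateral.offset,
        slope=peritumoral.slope / contralateral.slope,
        flags=tuple(flags))


def distance_subgroups(distances: Dict[str, float]) -> Dict[str, list]:
    """Split subjects into long (> 75th pct) and short (< 25th pct)
    mean-distance subgroups (linear-interpolation percentiles; strict
    inequalities, so boundary subjects belong to neither group)."""
    if len(distances) < 4:
        raise ValueError("need at least 4 subjects for quartile subgroups")
    ids = list(distances)
    vals = np.array([distances[s] for s in ids], dtype=float)
    q25, q75 = np.percentile(vals, [25, 75])
    return {"long": [s for s, v in zip(ids, vals) if v > q75],
            "short": [s for s, v in zip(ids, vals) if v < q25]}


def summarize_hemispheres(fits: Sequence, powers: np.ndarray,
                          atlas: RegionAtlas, tumor_hemisphere: str,
                          subject_id: str = ""):
    """Mean activity over the tumor hemisphere and over the other one.

    Returns ``(tumor_side, contralateral)`` activity summaries.
    """
    from .spectral import summarize_activity
    if tumor_hemisphere not in ("L", "R"):
        raise ValueError("tumor hemisphere must be 'L' or 'R'")
    other = "L" if tumor_hemisphere == "R" else "R"
    tumor = summarize_activity(fits, powers,
                               atlas.hemisphere_indices(tumor_hemisphere),
                               "hemisphere_tumor", subject_id=subject_id)
    contra = summarize_activity(fits, powers,
                                atlas.hemisphere_indices(other),
                                "hemisphere_contralateral",
                                subject_id=subject_id)
    return tumor, contra
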