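"""Synthetic mirror-symmetric cortical atlas.

Stands in for a volumetric cortical parcellation (by default 78 regions,
39 per hemisphere) with centroids in a head-centred coordinate frame in
millimetres: x increases to the right, the midsagittal plane is x = 0,
so the contralateral homologue of a region at (x, y, z) sits at
(-x, y, z).  The homologue mapping is a fixed-point-free involution and
homologue centroid pairs are exact mirror images, which downstream code
relies on when pairing peritumoral locations with their contralateral
counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Hemisphere bounding box (mm) for synthetic centroids; compact enough
# that a tumor-centred 30 mm rim search finds ten neighbours.
_BOX_X = (10.0, 55.0)
_BOX_Y = (-65.0, 65.0)
_BOX_Z = (-35.0, 50.0)

_MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class RegionAtlas:
    """Region identifiers, hemisphere labels, centroids and homologue map."""

    region_ids: tuple
    hemispheres: np.ndarray  # '<U1' array of 'L'/'R'
    centroids: np.ndarray    # (n, 3) float, mm
    homologues: np.ndarray   # (n,) int, index of the mirror region

    def __post_init__(self):
        n = len(self.region_ids)
        if self.centroids.shape != (n, 3):
            raise ValueError("centroids must be (n_regions, 3)")
        hom = self.homologues
        if np.any(hom == np.arange(n)):
            raise ValueError("homologue mapping must be fixed-point free")
        if not np.array_equal(hom[hom], np.arange(n)):
            raise ValueError("homologue mapping must be an involution")
        if not np.allclose(self.centroids[hom], self.centroids * _MIRROR):
            raise ValueError("homologue centroids must mirror about x = 0")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        """Indices of all regions in hemisphere 'L' or 'R'."""
        if hemisphere not in ("L", "R"):
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return np.flatnonzero(self.hemispheres == hemisphere)

    def homologue_of(self, index: int) -> int:
        return int(self.homologues[index])


def mirror_point(point) -> np.ndarray:
    """Mirror a coordinate about the midsagittal plane: (x,y,z) -> (-x,y,z)."""
    return np.asarray(point, dtype=float) * _MIRROR


def build_symmetric_atlas(n_regions: int = 78, seed: int = 2025) -> RegionAtlas:
    """Construct a deterministic symmetric atlas with ``n_regions`` regions.

    Right-hemisphere centroids are drawn uniformly in a hemisphere-sized
    box; left-hemisphere centroids are their exact mirror images.  Region
    indices 0..n/2-1 are left ('Lxx'), n/2..n-1 right ('Rxx'), and region
    i is the homologue of i + n/2.
    """
    if n_regions < 2 or n_regions % 2 != 0:
        raise ValueError("n_regions must be an even number >= 2 "
                         "(hemispheric pairing)")
    half = n_regions // 2
    rng = np.random.default_rng(seed)
    right = np.column_stack([
        rng.uniform(*_BOX_X, size=half),
        rng.uniform(*_BOX_Y, size=half),
        rng.uniform(*_BOX_Z, size=half),
    ])
    left = right * _MIRROR
    centroids = np.vstack([left, right])
    ids = tuple(f"L{i + 1:02d}" for i in range(half)) + \
        tuple(f"R{i + 1:02d}" for i in range(half))
    hemis = np.array(["L"] * half + ["R"] * half)
    hom = np.concatenate([np.arange(half) + half, np.arange(half)])
    return RegionAtlas(ids, hemis, centroids, hom)
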