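"""VOI definition and max/mean/peak extraction on parametric maps.

Lesions are delineated with an iterated 41%-of-maximum isocontour: the
connected component (26-connectivity) containing the seed among voxels at or
above 41% of the component maximum, with the maximum re-estimated until the
component is stable.  Normal organs use fixed-diameter spheres.  "Peak" is
the PERCIST-style neighbourhood value: the highest mean of a 1-cm³ sphere
centred on any VOI voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["VOI", "RegionStats", "segment_threshold41", "sphere_voi",
           "region_stats", "peak_sphere_means"]

#: radius (mm) of the 1-cm³ peak sphere: (3*1000 / 4π)^(1/3)
PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass(frozen=True)
class VOI:
    """A boolean mask over the image grid."""

    mask: np.ndarray
    kind: str                 # threshold41 | fixed_sphere
    anchor: tuple
    diameter_mm: float = 0.0

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("VOI is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RegionStats:
    max: float
    mean: float
    peak: float
    voxel_count: int


def segment_threshold41(map3d: np.ndarray, seed_voxel,
                        fraction: float = 0.41, max_iter: int = 20) -> VOI:
    """Iterated 41%-isocontour segmentation seeded inside a lesion."""
    seed = tuple(int(i) for i in seed_voxel)
    v0 = map3d[seed]
    if not np.isfinite(v0) or v0 <= 0:
        raise ValueError("seed voxel must lie on a positive, finite value")
    vol = np.nan_to_num(map3d, nan=-np.inf)
    current_max = float(v0)
    comp = None
    for _ in range(max_iter):
        above = vol >= fraction * current_max
        labels, _ = ndimage.label(above, structure=_STRUCT26)
        comp = labels == labels[seed]
        new_max = float(vol[comp].max())
        if new_max <= current_max * (1 + 1e-12):
            break
        current_max = new_max
    return VOI(comp, "threshold41", seed)


def sphere_voi(center_voxel, diameter_mm: float, grid_shape,
               voxel_size_mm: float) -> VOI:
    """Voxels whose centres lie within the sphere."""
    idx = np.indices(grid_shape, dtype=float)
    c = np.asarray(center_voxel, float).reshape(3, 1, 1, 1)
    d2 = (((idx - c) * voxel_size_mm) ** 2).sum(axis=0)
    mask = d2 <= (diameter_mm / 2.0) ** 2
    if not mask.any():
        raise ValueError("sphere does not intersect the grid")
    return VOI(mask, "fixed_sphere", tuple(int(i) for i in center_voxel),
               diameter_mm)


def _peak_kernel(voxel_size_mm: float) -> np.ndarray:
    r_vox = PEAK_RADIUS_MM / voxel_size_mm
    n = int(np.ceil(r_vox))
    g = np.indices((2 * n + 1,) * 3, dtype=float) - n
    return (g ** 2).sum(axis=0) <= r_vox ** 2


def peak_sphere_means(map3d: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Mean of the map over a 1-cm³ sphere centred at every voxel (NaN-aware)."""
    kernel = _peak_kernel(voxel_size_mm).astype(float)
    filled = np.nan_to_num(map3d, nan=0.0)
    valid = np.isfinite(map3d).astype(float)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def region_stats(map3d: np.ndarray, voi: VOI, voxel_size_mm: float,
                 sphere_means: np.ndarray | None = None) -> RegionStats:
    """Max, mean, and 1-cm³-sphere peak of a map over the VOI (NaN-aware).

    ``sphere_means`` may carry a precomputed :func:`peak_sphere_means`
    volume when many VOIs are read from one map.
    """
    vals = map3d[voi.mask]
    finite = np.isfinite(vals)
    if not finite.any():
        return RegionStats(np.nan, np.nan, np.nan, voi.voxel_count)
    vmax = float(vals[finite].max())
    vmean = float(vals[finite].mean())
    if sphere_means is None:
        sphere_means = peak_sphere_means(map3d, voxel_size_mm)
    vpeak = float(np.nanmax(sphere_means[voi.mask]))
    return RegionStats(vmax, vmean, vpeak, voi.voxel_count)
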