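"""Seeded 3D region growing inside a HU interval, structure subtraction,
nodule volume, and volume doubling time.

The region grower admits every voxel whose HU lies in a closed inclusion
interval (default [-450, +1500]) and keeps the connected component reachable
from the seed, optionally restricted to a half-open slice range.  Attached
structures (vessels, bronchi, scars) that fall inside the interval are
removed afterwards with an explicit exclusion mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume

#: default HU inclusion interval for solid nodules (closed on both ends)
DEFAULT_HU_INTERVAL = (-450, 1500)
#: growth is "stable" when the volume doubling time exceeds this (days)
VDT_STABLE_DAYS = 2000.0


@dataclass(frozen=True)
class SeedPoint:
    """Voxel coordinates (x, y, z); z is the slice index. 0-based."""
    x: int
    y: int
    z: int

    def as_index(self) -> tuple[int, int, int]:
        """(z, y, x) index into the voxel lattice."""
        return (self.z, self.y, self.x)


@dataclass
class SegmentationResult:
    mask: np.ndarray                       # boolean lattice, source frame
    voxel_count: int
    volume_mm3: float
    seed: SeedPoint
    hu_interval: tuple[float, float]
    spacing: tuple[float, float, float]
    connectivity: int = 6


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def _check_seed(volume: CTVolume, seed: SeedPoint) -> None:
    nz, ny, nx = volume.voxels.shape
    if not (0 <= seed.x < nx and 0 <= seed.y < ny and 0 <= seed.z < nz):
        raise IndexError("seed outside lattice")


def region_grow_3d(
    volume: CTVolume,
    seed: SeedPoint,
    hu_interval: tuple[float, float] = DEFAULT_HU_INTERVAL,
    connectivity: int = 6,
    slice_range: tuple[int, int] | None = None,
) -> SegmentationResult:
    """Grow the maximal connected in-interval region containing the seed.

    Parameters
    ----------
    hu_interval : closed inclusion interval (lo, hi) in HU.
    connectivity : 6 (face-adjacent, default) or 26 (face/edge/corner).
    slice_range : optional half-open [first, last) restriction on slice
        indices; must contain the seed slice.

    The result is deterministic: it equals the connected component of the
    thresholded lattice that contains the seed.
    """
    _check_seed(volume, seed)
    lo, hi = hu_interval
    if lo > hi:
        raise ValueError("hu_interval lower bound exceeds upper bound")
    seed_hu = volume.hu_at(seed.x, seed.y, seed.z)
    if not (lo <= seed_hu <= hi):
        raise ValueError("seed outside inclusion interval")

    in_interval = (volume.voxels >= lo) & (volume.voxels <= hi)
    if slice_range is not None:
        first, last = slice_range
        if not (first <= seed.z < last):
            raise ValueError("slice_range does not contain the seed slice")
        restricted = np.zeros_like(in_interval)
        restricted[max(first, 0):last] = in_interval[max(first, 0):last]
        in_interval = restricted

    labels, _ = ndimage.label(in_interval, structure=_structure(connectivity))
    seed_label = labels[seed.as_index()]
    mask = labels == seed_label

    count = int(mask.sum())
    dx, dy, dz = volume.spacing
    return SegmentationResult(
        mask=mask, voxel_count=count, volume_mm3=count * dx * dy * dz,
        seed=seed, hu_interval=(lo, hi), spacing=volume.spacing,
        connectivity=connectivity)


def subtract_structures(
    result: SegmentationResult, exclusion: np.ndarray
) -> SegmentationResult:
    """Remove excluded voxels (vessels, bronchi, scars) from a segmentation.

    After subtraction only the connected component containing the seed is
    retained, and counts/volumes are recomputed.  Excluding the seed voxel
    itself is an error.
    """
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != result.mask.shape:
        raise ValueError("exclusion lattice shape does not match mask")
    idx = result.seed.as_index()
    if exclusion[idx]:
        raise ValueError("seed removed by subtraction")
    remaining = result.mask & ~exclusion
    labels, _ = ndimage.label(remaining, structure=_structure(result.connectivity))
    mask = labels == labels[idx]
    count = int(mask.sum())
    dx, dy, dz = result.spacing
    return SegmentationResult(
        mask=mask, voxel_count=count, volume_mm3=count * dx * dy * dz,
        seed=result.seed, hu_interval=result.hu_interval,
        spacing=result.spacing, connectivity=result.connectivity)


def nodule_volume(
    result: SegmentationResult, spacing: tuple[float, float, float]
) -> float:
    """Physical nodule volume in mm^3: voxel count x dx x dy x dz."""
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("spacing must be positive")
    return result.voxel_count * dx * dy * dz


@dataclass
class GrowthAssessment:
    v1: float
    v2: float
    delta_t_days: float
    vdt_days: float       # math.inf when no growth
    stable: bool


def volume_doubling_time(
    v1: float, v2: float, delta_t_days: float
) -> GrowthAssessment:
    """Volume doubling time: VDT = dt * ln 2 / ln(v2/v1).

    No growth (v2 <= v1) is reported as an infinite VDT.  A nodule is
    considered stable when VDT > 2000 days (which includes any non-growing
    nodule).
    """
    if v1 <= 0 or v2 <= 0 or delta_t_days <= 0:
        raise ValueError("volumes and time interval must be positive")
    if v2 <= v1:
        vdt = math.inf
    else:
        vdt = delta_t_days * math.log(2.0) / math.log(v2 / v1)
    return GrowthAssessment(v1=v1, v2=v2, delta_t_days=delta_t_days,
                            vdt_days=vdt, stable=vdt > VDT_STABLE_DAYS)
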