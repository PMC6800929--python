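"""Nodule-volume HU density histogram and first-order texture statistics.

The histogram of a segmented nodule assigns each voxel's HU value to one of
``G`` bins; the normalized frequencies ``H(i) = counts(i) / n_voxels`` are
the weights in the moment formulas.  With unit-width bins centred on integer
HU values, moments computed from the histogram equal moments computed from
the raw voxel list exactly, which the package exploits as a dual-route
cross-check.

Statistics (population form, no small-sample correction):

    MEN = sum_i c_i H(i)
    VAR = sum_i (c_i - MEN)^2 H(i)
    SKW = sum_i (c_i - MEN)^3 H(i) / VAR^(3/2)
    KUR = sum_i (c_i - MEN)^4 H(i) / VAR^2 - 3      (excess kurtosis)

where ``c_i`` is the representative value of bin i.  A Gaussian density
scores KUR = 0; a peaked, heavy-tailed (leptokurtic) one scores above 0 and
a flat-topped (platykurtic) one below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import DEFAULT_HU_INTERVAL, SegmentationResult
from .volume_io import CTVolume


@dataclass
class NoduleHistogram:
    """HU density histogram of a segmented nodule volume.

    ``bin_edges`` has length G+1 and is strictly increasing; edges sit on
    half-integers so that unit-width bins are centred on integer HU values.
    Bins are half-open [edge, edge+width) except the last, which includes
    its upper edge.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def G(self) -> int:
        return len(self.counts)

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def H(self) -> np.ndarray:
        """Normalized frequencies; sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FirstOrderStats:
    MEN: float   # HU
    VAR: float   # HU^2
    SKW: float   # dimensionless
    KUR: float   # dimensionless (excess)


def build_histogram(
    volume: CTVolume,
    mask: SegmentationResult | np.ndarray,
    bin_width: float = 1.0,
    hu_range: tuple[float, float] = DEFAULT_HU_INTERVAL,
) -> NoduleHistogram:
    """Histogram the HU values of the masked voxels.

    Bin edges run from ``lo - bin_width/2`` upward in steps of ``bin_width``
    until ``hi`` is covered, so at unit width each bin is centred on an
    integer HU value.  All masked voxels must lie within ``hu_range`` (this
    is guaranteed when the mask came from region growing with the same
    interval).
    """
    mask_arr = mask.mask if isinstance(mask, SegmentationResult) else np.asarray(mask, bool)
    values = np.asarray(volume.voxels[mask_arr], dtype=float)
    if values.size == 0:
        raise ValueError("empty segmentation")
    lo, hi = hu_range
    if values.min() < lo or values.max() > hi:
        raise ValueError("masked voxels outside histogram range")
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    edges = lo - bin_width / 2.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return NoduleHistogram(bin_edges=edges, counts=counts.astype(np.int64))


def mean_hu(hist: NoduleHistogram) -> float:
    """MEN: histogram-weighted mean HU."""
    return float(np.sum(hist.centers * hist.H))


def variance_hu(hist: NoduleHistogram) -> float:
    """VAR: population variance of the HU distribution (no bias correction)."""
    men = mean_hu(hist)
    return float(np.sum((hist.centers - men) ** 2 * hist.H))


def _standardized_moment(hist: NoduleHistogram, order: int,
                         literal_exponents: bool) -> float:
    men = mean_hu(hist)
    var = variance_hu(hist)
    if var == 0.0:
        raise ValueError("degenerate distribution")
    mu = float(np.sum((hist.centers - men) ** order * hist.H))
    if literal_exponents:
        # as-printed normalisation (VAR^3 for skewness, VAR^4 for kurtosis);
        # kept only for auditing the published formulas
        return mu / var ** order
    return mu / var ** (order / 2.0)


def skewness(hist: NoduleHistogram, literal_exponents: bool = False) -> float:
    """SKW: third standardized moment (asymmetry of the HU distribution)."""
    return _standardized_moment(hist, 3, literal_exponents)


def kurtosis(hist: NoduleHistogram, fisher: bool = True,
             literal_exponents: bool = False) -> float:
    """KUR: fourth standardized moment.

    By default the excess (Fisher) form is returned, i.e. 3 is subtracted so
    that a Gaussian scores 0; ``fisher=False`` gives the raw fourth moment
    ratio.
    """
    m4 = _standardized_moment(hist, 4, literal_exponents)
    return m4 - 3.0 if fisher else m4


def stats_from_histogram(hist: NoduleHistogram) -> FirstOrderStats:
    return FirstOrderStats(MEN=mean_hu(hist), VAR=variance_hu(hist),
                           SKW=skewness(hist), KUR=kurtosis(hist))


def stats_from_voxels(
    volume: CTVolume, mask: SegmentationResult | np.ndarray
) -> FirstOrderStats:
    """First-order statistics computed directly from the voxel list.

    Cross-check path: identical to the histogram path at unit bin width for
    integer HU input.
    """
    mask_arr = mask.mask if isinstance(mask, SegmentationResult) else np.asarray(mask, bool)
    values = np.asarray(volume.voxels[mask_arr], dtype=float)
    if values.size == 0:
        raise ValueError("empty segmentation")
    men = float(values.mean())
    dev = values - men
    var = float(np.mean(dev ** 2))
    if var == 0.0:
        raise ValueError("degenerate distribution")
    skw = float(np.mean(dev ** 3)) / var ** 1.5
    kur = float(np.mean(dev ** 4)) / var ** 2 - 3.0
    return FirstOrderStats(MEN=men, VAR=var, SKW=skw, KUR=kur)
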