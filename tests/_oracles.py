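"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np

_FACE_NEIGHBOURS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_ALL_NEIGHBOURS = [(dz, dy, dx)
                   for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]


def bfs_flood_fill(voxels, seed_zyx, lo, hi, connectivity=6,
                   slice_range=None):
    """Breadth-first flood fill over in-interval voxels; returns a mask."""
    voxels = np.asarray(voxels)
    mask = np.zeros(voxels.shape, dtype=bool)
    nz, ny, nx = voxels.shape
    offsets = _FACE_NEIGHBOURS if connectivity == 6 else _ALL_NEIGHBOURS

    def allowed(z, y, x):
        if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
            return False
        if slice_range is not None and not (slice_range[0] <= z < slice_range[1]):
            return False
        return lo <= voxels[z, y, x] <= hi

    if not allowed(*seed_zyx):
        raise ValueError("seed not admissible")
    queue = deque([seed_zyx])
    mask[seed_zyx] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nzz, nyy, nxx = z + dz, y + dy, x + dx
            if allowed(nzz, nyy, nxx) and not mask[nzz, nyy, nxx]:
                mask[nzz, nyy, nxx] = True
                queue.append((nzz, nyy, nxx))
    return mask


def moments_oracle(values):
    """(MEN, VAR, SKW, KUR) from a raw value list, plain-python arithmetic."""
    values = [float(v) for v in values]
    n = len(values)
    men = sum(values) / n
    var = sum((v - men) ** 2 for v in values) / n
    mu3 = sum((v - men) ** 3 for v in values) / n
    mu4 = sum((v - men) ** 4 for v in values) / n
    return men, var, mu3 / var ** 1.5, mu4 / var ** 2 - 3.0


def pairwise_auc(scores, labels):
    """AUC by exhaustive pair counting; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def trapezoid_area(points):
    """Area under a piecewise-linear ROC curve given (fpr, tpr) points."""
    pts = sorted(map(tuple, points))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def icc21_anova(a, b):
    """ICC(2,1) from two-way ANOVA mean squares (subjects x raters)."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
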