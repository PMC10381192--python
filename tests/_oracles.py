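"""Independent brute-force oracles used by the test suite.

These are deliberately written in plain loops, separate from the package's
vectorised implementations, so that agreement between the two routes is a
meaningful check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def icc_oneway_oracle(y, alpha: float = 0.05):
    """Spreadsheet-style one-way ANOVA ICC(1,1) with F-based 95% CI."""
    y = [[float(v) for v in row] for row in np.asarray(y)]
    n = len(y)
    k = len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    row_means = [sum(row) / k for row in y]
    ssb = sum(k * (m - grand) ** 2 for m in row_means)
    ssw = 0.0
    for i in range(n):
        for j in range(k):
            ssw += (y[i][j] - row_means[i]) ** 2
    df1 = n - 1
    df2 = n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    est = (msb - msw) / (msb + (k - 1) * msw)
    f0 = msb / msw
    fl = f0 / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * sps.f.ppf(1 - alpha / 2, df2, df1)
    lower = (fl - 1) / (fl + k - 1)
    upper = (fu - 1) / (fu + k - 1)
    return est, lower, upper


def glcm_matrix_oracle(volume, direction, n_levels):
    """Symmetric co-occurrence counts by explicit voxel-pair enumeration.

    ``volume`` holds grey levels 1..n_levels with 0 outside the ROI.
    """
    vol = np.asarray(volume)
    mat = np.zeros((n_levels, n_levels))
    dx, dy, dz = direction
    nx, ny, nz = vol.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = vol[x, y, z]
                if a == 0:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                b = vol[x2, y2, z2]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def glrlm_matrix_oracle(volume, direction, n_levels):
    """Run-length counts by explicit line walking."""
    vol = np.asarray(volume)
    shape = vol.shape
    d = tuple(direction)
    runs: dict[tuple[int, int], int] = {}

    def in_bounds(p):
        return all(0 <= p[i] < shape[i] for i in range(3))

    visited = set()
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                p = (x, y, z)
                if vol[p] == 0 or p in visited:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if in_bounds(prev) and vol[prev] == vol[p]:
                    continue  # not a run start
                length = 0
                q = p
                while in_bounds(q) and vol[q] == vol[p]:
                    visited.add(q)
                    length += 1
                    q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                key = (int(vol[p]) - 1, length - 1)
                runs[key] = runs.get(key, 0) + 1
    max_len = max((ln for _, ln in runs), default=0) + 1
    mat = np.zeros((n_levels, max_len))
    for (lv, ln), c in runs.items():
        mat[lv, ln] = c
    return mat


def dice_oracle(a, b) -> float:
    """Voxel-by-voxel dice count."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    inter = sum(1 for x, y in zip(a, b) if x and y)
    na = sum(1 for x in a if x)
    nb = sum(1 for x in b if x)
    if na + nb == 0:
        return math.nan
    return 2 * inter / (na + nb)
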