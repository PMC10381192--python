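"""Grey-level texture matrices and their feature vectors.

GLCM (22 features) and GLRLM (16) are built per direction over the 13 unique
3D lattice directions, with feature values averaged across directions. GLSZM
(16) uses a single matrix with 26-connected zones. Inputs are label volumes
where 0 marks out-of-ROI voxels and in-ROI voxels carry grey levels 1..Ng.

Degenerate matrices (single grey level, single voxel) evaluate features by
their finite limits where those exist (entropies -> 0) and by the reference
extractor's conventions otherwise; callers can detect the single-level case
via ``n_levels == 1``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

DIRECTIONS_13 = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def _pair_slices(shape, d):
    """Slices (sa, sb) so arr[sa] and arr[sb] pair each voxel v with v+d."""
    sa, sb = [], []
    for n, off in zip(shape, d):
        if off >= 0:
            sa.append(slice(0, n - off))
            sb.append(slice(off, n))
        else:
            sa.append(slice(-off, n))
            sb.append(slice(0, n + off))
    return tuple(sa), tuple(sb)


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """arr evaluated at v+d, with ``fill`` outside the grid."""
    out = np.full_like(arr, fill)
    sa, sb = _pair_slices(arr.shape, d)
    out[sa] = arr[sb]
    return out


# --- GLCM -------------------------------------------------------------------


def glcm_matrix(labels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence matrix for one direction (counts)."""
    sa, sb = _pair_slices(labels.shape, direction)
    a, b = labels[sa].ravel(), labels[sb].ravel()
    ok = (a > 0) & (b > 0)
    a, b = a[ok] - 1, b[ok] - 1
    mat = np.bincount(a * n_levels + b, minlength=n_levels**2).reshape(n_levels, n_levels)
    return (mat + mat.T).astype(float)


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence features of one normalised symmetric matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # diagonal / cross-diagonal marginals
    p_sum = np.bincount((I + J).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(np.abs(I - J).ravel(), weights=p.ravel(), minlength=ng)[:ng]

    diff_avg = float((k_diff * p_diff).sum())

    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    if sig_x > 0:
        corr = float(((I * J * p).sum() - mu_x * mu_x) / (sig_x * sig_x))
    else:
        corr = 1.0  # reference-extractor convention for a flat matrix
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    off = I != J
    inv_var = float((p[off] / (I[off] - J[off]) ** 2).sum())

    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float(((I + J - 2 * mu_x) ** 4 * p).sum()),
        "ClusterShade": float(((I + J - 2 * mu_x) ** 3 * p).sum()),
        "ClusterTendency": float(((I + J - 2 * mu_x) ** 2 * p).sum()),
        "Contrast": float(((I - J) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float(((I - mu_x) ** 2 * p).sum()),
    }


def glcm_features(labels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged GLCM features over the 13 unique 3D directions."""
    acc = {name: 0.0 for name in GLCM_NAMES}
    used = 0
    for d in DIRECTIONS_13:
        mat = glcm_matrix(labels, n_levels, d)
        tot = mat.sum()
        if tot == 0:
            continue
        feats = glcm_features_from_matrix(mat / tot)
        for name in GLCM_NAMES:
            acc[name] += feats[name]
        used += 1
    if used == 0:  # single voxel: no pairs in any direction
        out = {name: 0.0 for name in GLCM_NAMES}
        out["Correlation"] = 1.0
        return out
    return {name: acc[name] / used for name in GLCM_NAMES}


# --- run-length / size-zone shared formulas ---------------------------------


def _distribution_features(P: np.ndarray, np_voxels: int, names: tuple[str, ...]) -> dict[str, float]:
    """The 16 shared grey-level/size-distribution features.

    ``P[i, s]`` counts runs (or zones) of grey level i+1 and length (size) s+1;
    ``names`` supplies the family-specific labels in canonical order.
    """
    ns = P.sum()
    if ns == 0:
        return {name: 0.0 for name in names}
    ng, smax = P.shape
    i = np.arange(1, ng + 1, dtype=float)
    s = np.arange(1, smax + 1, dtype=float)
    I, S = np.meshgrid(i, s, indexing="ij")
    p = P / ns
    gl_sum = P.sum(axis=1)
    sz_sum = P.sum(axis=0)
    mu_i = float((I * p).sum())
    mu_s = float((S * p).sum())
    p_nz = p[p > 0]
    vals = (
        float((P / S**2).sum() / ns),
        float((P * S**2).sum() / ns),
        float((gl_sum**2).sum() / ns),
        float((gl_sum**2).sum() / ns**2),
        float((sz_sum**2).sum() / ns),
        float((sz_sum**2).sum() / ns**2),
        float(ns / np_voxels),
        float((p * (I - mu_i) ** 2).sum()),
        float((p * (S - mu_s) ** 2).sum()),
        float(-(p_nz * np.log2(p_nz + _EPS)).sum()),
        float((P / I**2).sum() / ns),
        float((P * I**2).sum() / ns),
        float((P / (I**2 * S**2)).sum() / ns),
        float((P * I**2 / S**2).sum() / ns),
        float((P * S**2 / I**2).sum() / ns),
        float((P * I**2 * S**2).sum() / ns),
    )
    return dict(zip(names, vals))


# --- GLRLM ------------------------------------------------------------------


def glrlm_matrix(labels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts P[level, length] along one direction."""
    g = labels
    in_roi = g > 0
    nxt = _shift(g, direction)
    same_next = in_roi & (nxt == g) & (_shift(in_roi.astype(np.uint8), direction) > 0)
    # L[v] = remaining run length starting at v (forward along direction)
    L = in_roi.astype(np.int64)
    while True:
        Ln = np.where(same_next, _shift(L, direction) + 1, in_roi.astype(np.int64))
        if np.array_equal(Ln, L):
            break
        L = Ln
    back = tuple(-o for o in direction)
    prev = _shift(g, back)
    prev_in = _shift(in_roi.astype(np.uint8), back) > 0
    starts = in_roi & ~(prev_in & (prev == g))
    if not starts.any():
        return np.zeros((n_levels, 1))
    lv = g[starts] - 1
    ln = L[starts] - 1
    max_len = int(ln.max()) + 1
    P = np.bincount(lv * max_len + ln, minlength=n_levels * max_len)
    return P.reshape(n_levels, max_len).astype(float)


def glrlm_features(labels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged run-length features over the 13 directions."""
    np_voxels = int((labels > 0).sum())
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for d in DIRECTIONS_13:
        feats = _distribution_features(glrlm_matrix(labels, n_levels, d), np_voxels, GLRLM_NAMES)
        for name in GLRLM_NAMES:
            acc[name] += feats[name]
    return {name: acc[name] / len(DIRECTIONS_13) for name in GLRLM_NAMES}


# --- GLSZM ------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts P[level, size] with 26-connected zones."""
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for lv in range(1, n_levels + 1):
        comp, n = ndimage.label(labels == lv, structure=_STRUCT_26)
        if n == 0:
            sizes_per_level.append(np.zeros(0, dtype=np.int64))
            continue
        sizes = np.bincount(comp.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((n_levels, max_size))
    for lv, sizes in enumerate(sizes_per_level):
        if sizes.size:
            counts = np.bincount(sizes - 1, minlength=max_size)
            P[lv, :] = counts
    return P


def glszm_features(labels: np.ndarray, n_levels: int) -> dict[str, float]:
    np_voxels = int((labels > 0).sum())
    return _distribution_features(glszm_matrix(labels, n_levels), np_voxels, GLSZM_NAMES)
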