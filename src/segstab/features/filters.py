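"""The 17-variant image filter bank.

Variants, in stable order: ``original``; Laplacian-of-Gaussian at physical
sigmas (default 2, 3, 4, 5 mm); the eight single-level separable wavelet
decompositions (undecimated Haar, high/low pass per axis, labelled
``wavelet-HHH`` ... ``wavelet-LLL``); ``square``; ``squareroot``;
``logarithm``; ``exponential``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..core import GeometryError, VolumeImage

# orthonormal Haar pair; L sums to sqrt(2), so LLL maps a constant c to 2^1.5 c
_HAAR_L = np.array([1.0, 1.0]) / np.sqrt(2.0)
_HAAR_H = np.array([1.0, -1.0]) / np.sqrt(2.0)

WAVELET_LABELS = ("HHH", "HHL", "HLH", "HLL", "LHH", "LHL", "LLH", "LLL")


def log_filter(img: VolumeImage, sigma_mm: float) -> VolumeImage:
    """Laplacian of Gaussian with a physical-unit kernel width.

    Requires an isotropic grid (apply after resampling).
    """
    sp = img.spacing
    if not np.allclose(sp, sp[0]):
        raise GeometryError(f"LoG requires isotropic spacing, got {sp}")
    sigma_vox = sigma_mm / sp[0]
    arr = np.asarray(img.data, dtype=float)
    out = ndimage.gaussian_laplace(arr, sigma_vox)
    # remove the truncated kernel's small DC leak so constants map to 0 exactly
    m = 2 * int(np.ceil(4 * sigma_vox)) + 5
    probe = ndimage.gaussian_laplace(np.ones((m, m, m)), sigma_vox)
    dc = float(probe[m // 2, m // 2, m // 2])
    return img.copy_with(out - dc * arr)


def wavelet_decompositions(img: VolumeImage) -> dict[str, VolumeImage]:
    """All eight single-level separable high/low-pass combinations."""
    arr = np.asarray(img.data, dtype=float)
    out: dict[str, VolumeImage] = {}
    for label in WAVELET_LABELS:
        cur = arr
        for axis, ch in enumerate(label):
            kernel = _HAAR_H if ch == "H" else _HAAR_L
            cur = ndimage.correlate1d(cur, kernel, axis=axis, mode="reflect")
        out[label] = img.copy_with(cur)
    return out


def _absmax(arr: np.ndarray) -> float:
    return float(np.max(np.abs(arr)))


def square_filter(img: VolumeImage) -> VolumeImage:
    """x^2 rescaled back onto the input's absolute range."""
    arr = np.asarray(img.data, dtype=float)
    m = _absmax(arr)
    if m == 0:
        return img.copy_with(np.zeros_like(arr))
    return img.copy_with(arr**2 / m)


def squareroot_filter(img: VolumeImage) -> VolumeImage:
    """sign(x) * sqrt(|x| * max|x|) — sqrt stretched onto the input range."""
    arr = np.asarray(img.data, dtype=float)
    m = _absmax(arr)
    return img.copy_with(np.sign(arr) * np.sqrt(np.abs(arr) * m))


def logarithm_filter(img: VolumeImage) -> VolumeImage:
    """sign(x) * log(|x| + 1), rescaled onto the input's absolute range."""
    arr = np.asarray(img.data, dtype=float)
    f = np.sign(arr) * np.log1p(np.abs(arr))
    fm = _absmax(f)
    if fm == 0:
        return img.copy_with(np.zeros_like(arr))
    return img.copy_with(f * _absmax(arr) / fm)


def exponential_filter(img: VolumeImage) -> VolumeImage:
    """exp(c x) with c = ln(max|x|) / max|x|, so the output peaks at max|x|."""
    arr = np.asarray(img.data, dtype=float)
    m = _absmax(arr)
    if m == 0:
        return img.copy_with(np.ones_like(arr))
    c = np.log(m) / m
    return img.copy_with(np.exp(c * arr))


def filter_bank(
    img: VolumeImage, log_sigmas: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
) -> dict[str, VolumeImage]:
    """Ordered map of the 17 labelled image variants (original included)."""
    out: dict[str, VolumeImage] = {"original": img}
    for s in log_sigmas:
        out[f"log-sigma-{s:g}mm"] = log_filter(img, s)
    for label, wav in wavelet_decompositions(img).items():
        out[f"wavelet-{label}"] = wav
    out["square"] = square_filter(img)
    out["squareroot"] = squareroot_filter(img)
    out["logarithm"] = logarithm_filter(img)
    out["exponential"] = exponential_filter(img)
    return out
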