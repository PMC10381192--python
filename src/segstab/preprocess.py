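"""Derived-map computation, resampling and intensity normalization.

The processing chain is: derived maps (ADC, DCE subtraction) in native space,
resampling to an isotropic grid (cubic in-plane, nearest-neighbour
through-plane; nearest-neighbour everywhere for masks), then ROI-based
z-normalization with 3-sigma clipping and a 300/100 mean/std rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DynamicSeries, GeometryError, VolumeImage

__all__ = [
    "PreprocessConfig",
    "DynamicSeries",
    "compute_adc_map",
    "compute_sub_maps",
    "resample_image",
    "resample_mask",
    "normalize_roi",
    "normalize_population",
]


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    clip_sigma: float = 3.0
    target_mean: float = 300.0
    target_std: float = 100.0
    sub_split_time: float = 90.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise GeometryError("target_spacing must be positive")
        if self.clip_sigma <= 0 or self.target_std <= 0:
            raise ValueError("clip_sigma and target_std must be positive")


# --- derived maps -----------------------------------------------------------


def compute_adc_map(
    dwi_stack: list[VolumeImage], b_values, qc: dict | None = None
) -> VolumeImage:
    """Voxelwise ADC (mm^2/s) as minus the OLS slope of ln S versus b.

    Nonpositive samples are floored at the smallest positive signal in the
    stack before taking logs; voxels whose signals are all nonpositive get
    ADC = 0 and are counted in ``qc['adc_zeroed_voxels']``.
    """
    b = np.asarray(b_values, dtype=float)
    if len(b) != len(dwi_stack):
        raise ValueError("one b-value per DWI volume required")
    if len(np.unique(b)) < 2:
        raise ValueError("need >= 2 distinct b-values")
    grid = dwi_stack[0]
    for v in dwi_stack[1:]:
        grid.require_same_grid(v)
    sig = np.stack([v.data for v in dwi_stack], axis=-1).astype(float)

    pos = sig > 0
    all_bad = ~pos.any(axis=-1)
    floor = sig[pos].min() if pos.any() else 1.0
    logs = np.log(np.where(pos, sig, floor))

    # OLS slope of ln S on b, identical weights at every voxel
    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = np.tensordot(logs, bc, axes=([-1], [0])) / denom
    adc = -slope
    adc[all_bad] = 0.0
    if qc is not None:
        qc["adc_zeroed_voxels"] = int(all_bad.sum())
    return grid.copy_with(adc)


def split_frame_index(times: np.ndarray, split_time: float) -> int:
    """Earliest acquisition at or after ``split_time`` (nonnegative epsilon)."""
    idx = np.flatnonzero(np.asarray(times, dtype=float) >= split_time)
    if len(idx) == 0 or idx[0] >= len(times) - 1 or idx[0] == 0:
        raise ValueError(
            f"no usable split frame strictly between first and last "
            f"acquisition for split time {split_time}s (times {list(times)})"
        )
    return int(idx[0])


def compute_sub_maps(
    dce: DynamicSeries, config: PreprocessConfig | None = None
) -> tuple[VolumeImage, VolumeImage]:
    """Wash-in and wash-out subtraction maps around the configured split time.

    ``sub_win = frame(t_split) - frame(t_0)``,
    ``sub_wout = frame(t_n) - frame(t_split)``.
    """
    config = config or PreprocessConfig()
    if len(dce) < 3:
        raise ValueError("subtraction maps need >= 3 frames")
    k = split_frame_index(dce.times, config.sub_split_time)
    grid = dce.grid
    sub_win = grid.copy_with(dce.frames[k].data - dce.frames[0].data)
    sub_wout = grid.copy_with(dce.frames[-1].data - dce.frames[k].data)
    return sub_win, sub_wout


# --- resampling -------------------------------------------------------------


def _axis_coords(n_old: int, old_sp: float, new_sp: float) -> np.ndarray:
    n_new = max(1, int(round(n_old * old_sp / new_sp)))
    return np.arange(n_new) * (new_sp / old_sp)


def _resample_arr(
    arr: np.ndarray,
    old_spacing: tuple[float, float, float],
    new_spacing: tuple[float, float, float],
    inplane_order: int,
    outplane_order: int,
) -> np.ndarray:
    cx = _axis_coords(arr.shape[0], old_spacing[0], new_spacing[0])
    cy = _axis_coords(arr.shape[1], old_spacing[1], new_spacing[1])
    cz = _axis_coords(arr.shape[2], old_spacing[2], new_spacing[2])
    # pass 1: in-plane
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    pass1 = np.empty((len(cx), len(cy), arr.shape[2]), dtype=float)
    for k in range(arr.shape[2]):
        pass1[:, :, k] = ndimage.map_coordinates(
            arr[:, :, k].astype(float), [gx, gy], order=inplane_order, mode="nearest"
        )
    # pass 2: through-plane
    if outplane_order == 0:
        zi = np.clip(np.round(cz).astype(int), 0, arr.shape[2] - 1)
        return pass1[:, :, zi]
    gz = np.broadcast_to(cz, (len(cx), len(cy), len(cz)))
    gi, gj = np.meshgrid(np.arange(len(cx)), np.arange(len(cy)), indexing="ij")
    coords = [
        np.broadcast_to(gi[..., None], gz.shape),
        np.broadcast_to(gj[..., None], gz.shape),
        gz,
    ]
    return ndimage.map_coordinates(pass1, coords, order=outplane_order, mode="nearest")


def resample_image(
    img: VolumeImage, config: PreprocessConfig | None = None, kind: str = "intensity"
) -> VolumeImage:
    """Resample to ``config.target_spacing``.

    Intensity images use cubic B-spline in-plane then nearest-neighbour
    through-plane; masks use nearest-neighbour on every axis and stay binary.
    """
    config = config or PreprocessConfig()
    if kind not in ("intensity", "mask"):
        raise ValueError("kind must be 'intensity' or 'mask'")
    target = config.target_spacing
    if kind == "mask":
        out = _resample_arr(np.asarray(img.data, dtype=float), img.spacing, target, 0, 0)
        return BinaryMask((out > 0.5).astype(np.uint8), target, img.origin)
    out = _resample_arr(np.asarray(img.data, dtype=float), img.spacing, target, 3, 0)
    return VolumeImage(out, target, img.origin)


def resample_mask(mask: BinaryMask, config: PreprocessConfig | None = None) -> BinaryMask:
    return resample_image(mask, config, kind="mask")  # type: ignore[return-value]


# --- normalization ----------------------------------------------------------


def _apply_norm(
    arr: np.ndarray, mean: float, std: float, config: PreprocessConfig
) -> tuple[np.ndarray, float]:
    z = (arr - mean) / std
    clipped_frac = float(np.mean(np.abs(z) > config.clip_sigma))
    z = np.clip(z, -config.clip_sigma, config.clip_sigma)
    return z * config.target_std + config.target_mean, clipped_frac


def normalize_roi(
    img: VolumeImage,
    mask: BinaryMask,
    config: PreprocessConfig | None = None,
    qc: dict | None = None,
    subject: str = "",
) -> VolumeImage:
    """Z-normalize using the ROI mean/std, clip at ``clip_sigma``, rescale.

    With defaults the unclipped output occupies [0, 600] with ROI mean 300
    and std 100.
    """
    config = config or PreprocessConfig()
    img.require_same_grid(mask)
    roi = img.data[mask.data > 0]
    if roi.size == 0:
        raise ValueError(f"empty ROI{' for ' + subject if subject else ''}")
    std = float(roi.std())
    if std == 0:
        raise ValueError(f"ROI std is zero{' for ' + subject if subject else ''}")
    out, frac = _apply_norm(np.asarray(img.data, dtype=float), float(roi.mean()), std, config)
    if qc is not None:
        qc[f"clip_fraction{'_' + subject if subject else ''}"] = frac
    return img.copy_with(out)


def normalize_population(
    imgs: list[VolumeImage],
    masks: list[BinaryMask],
    config: PreprocessConfig | None = None,
    qc: dict | None = None,
    stats: tuple[float, float] | None = None,
) -> list[VolumeImage]:
    """Normalize every subject with one pooled ROI mean/std.

    ``stats`` may supply frozen (mean, std) from a reference cohort; otherwise
    they are pooled over all subjects' ROI voxels.
    """
    config = config or PreprocessConfig()
    if not imgs or len(imgs) != len(masks):
        raise ValueError("need equally many images and masks, at least one")
    for im, mk in zip(imgs, masks):
        im.require_same_grid(mk)
    if stats is None:
        pooled = np.concatenate([im.data[mk.data > 0] for im, mk in zip(imgs, masks)])
        if pooled.size == 0:
            raise ValueError("no ROI voxels in the population")
        mean, std = float(pooled.mean()), float(pooled.std())
    else:
        mean, std = stats
    if std == 0:
        raise ValueError("pooled ROI std is zero")
    out = []
    for i, im in enumerate(imgs):
        arr, frac = _apply_norm(np.asarray(im.data, dtype=float), mean, std, config)
        if qc is not None:
            qc[f"clip_fraction_subject{i}"] = frac
        out.append(im.copy_with(arr))
    return out
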