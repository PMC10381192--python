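"""Bounded contour perturbation of 3D binary masks.

Simulates segmentation variability by perturbing each axial slice of a mask
(in-plane width/height change plus a small rotation) and/or shifting the
superior/inferior boundary-slice choice by at most one slice. Perturbation
directions can be drawn independently per slice (random bias) or held
sign-consistent across slices (systematic bias), mimicking annotators with a
liberal or conservative tendency.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BinaryMask

SCENARIOS = ("in_plane", "out_plane", "in_out_plane")
BIASES = ("random", "systematic")


@dataclass
class AugmentationConfig:
    """Bounds and mode of the contour generator.

    ``dw_bound``/``dh_bound`` bound the width/height change per slice (mm),
    ``alpha_bound`` the in-plane rotation (degrees), ``slice_shift_max`` the
    boundary-slice shift (slices). ``translation_bound`` (mm) enables an
    optional in-plane centroid shift and is off by default.
    """

    dw_bound: float = 2.7
    dh_bound: float = 2.7
    alpha_bound: float = 5.0
    slice_shift_max: int = 1
    scenario: str = "in_out_plane"
    bias: str = "random"
    n_contours: int = 15
    translation_bound: float = 0.0
    rotation_per_slice_random: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dw_bound, self.dh_bound, self.alpha_bound,
               self.translation_bound) < 0 or self.slice_shift_max < 0:
            raise ValueError("all perturbation bounds must be >= 0")
        if self.n_contours < 1:
            raise ValueError("n_contours must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.bias not in BIASES:
            raise ValueError(f"bias must be one of {BIASES}")


@dataclass
class SliceParams:
    """Per-slice in-plane perturbation: dimension deltas (mm) and rotation."""

    slice_index: int
    dw: float = 0.0
    dh: float = 0.0
    alpha: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    applied_scale_x: float = 1.0
    applied_scale_y: float = 1.0

    @property
    def is_identity(self) -> bool:
        return self.dw == self.dh == self.alpha == self.tx == self.ty == 0.0


@dataclass
class ContourLog:
    """Full parameter record for one generated contour."""

    slice_params: list[SliceParams] = field(default_factory=list)
    delta_sup: int = 0
    delta_inf: int = 0


@dataclass
class AugmentedMaskSet:
    """Ground-truth mask, k perturbed masks, and the complete parameter log."""

    ground_truth: BinaryMask
    perturbed: list[BinaryMask]
    logs: list[ContourLog]
    config: AugmentationConfig
    seed: int

    def __post_init__(self) -> None:
        for m in self.perturbed:
            self.ground_truth.require_same_grid(m)
        if len(self.perturbed) != len(self.logs):
            raise ValueError("one log per perturbed contour required")

    def save_log(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "scenario": self.config.scenario,
            "bias": self.config.bias,
            "config": asdict(self.config),
            "contours": [
                {
                    "delta_sup": log.delta_sup,
                    "delta_inf": log.delta_inf,
                    "slices": [asdict(sp) for sp in log.slice_params],
                }
                for log in self.logs
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# --- dice -------------------------------------------------------------------


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); NaN when both masks are empty."""
    a.require_same_grid(b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        return float("nan")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


# --- parameter sampling -----------------------------------------------------


def _truncated_uniform(
    rng: np.random.Generator, lo: float, hi: float, floor: np.ndarray
) -> np.ndarray:
    """U(lo, hi) draws conditioned elementwise on exceeding ``floor``.

    Used to keep a perturbed slice dimension positive: for tiny boundary
    slices the negative tail below ``-dimension`` is unreachable, so the draw
    is from the truncated law on (floor, hi].
    """
    n = len(floor)
    vals = rng.uniform(lo, hi, n)
    bad = vals <= floor
    for _ in range(200):
        if not bad.any():
            break
        vals[bad] = rng.uniform(lo, hi, int(bad.sum()))
        bad = vals <= floor
    if bad.any():  # floor >= hi: no valid draw exists
        raise ValueError("slice dimension too small for the perturbation bound")
    return vals


def sample_inplane_params(
    config: AugmentationConfig,
    slice_indices: np.ndarray,
    bias: str,
    rng: np.random.Generator,
    min_dims: dict[int, tuple[float, float]] | None = None,
) -> list[SliceParams]:
    """Draw per-slice in-plane parameters under the given bias.

    random bias: dw, dh, alpha ~ U(-bound, +bound) independently per slice.
    systematic bias: one sign per contour for each of dw/dh/alpha; magnitudes
    drawn per slice from U(0, bound).

    ``min_dims`` maps slice index to the slice's (width, height) in mm; when
    given, dw/dh draws are conditioned on keeping the perturbed dimension
    positive (relevant only for boundary slices narrower than the bound).
    """
    if bias not in BIASES:
        raise ValueError(f"bias must be one of {BIASES}")
    n = len(slice_indices)
    if min_dims is not None:
        w_floor = np.array([-min_dims[int(k)][0] for k in slice_indices])
        h_floor = np.array([-min_dims[int(k)][1] for k in slice_indices])
    else:
        w_floor = np.full(n, -np.inf)
        h_floor = np.full(n, -np.inf)
    out: list[SliceParams] = []
    if bias == "random":
        dw = _truncated_uniform(rng, -config.dw_bound, config.dw_bound, w_floor) \
            if config.dw_bound else np.zeros(n)
        dh = _truncated_uniform(rng, -config.dh_bound, config.dh_bound, h_floor) \
            if config.dh_bound else np.zeros(n)
        if config.alpha_bound:
            if config.rotation_per_slice_random:
                al = rng.uniform(-config.alpha_bound, config.alpha_bound, n)
            else:
                al = np.full(n, rng.uniform(-config.alpha_bound, config.alpha_bound))
        else:
            al = np.zeros(n)
        tx = rng.uniform(-config.translation_bound, config.translation_bound, n) \
            if config.translation_bound else np.zeros(n)
        ty = rng.uniform(-config.translation_bound, config.translation_bound, n) \
            if config.translation_bound else np.zeros(n)
    else:  # systematic: signs fixed per contour, magnitudes per slice
        s_dw, s_dh, s_al = (rng.choice((-1.0, 1.0)) for _ in range(3))
        def _signed_magnitudes(sign: float, bound: float, floor: np.ndarray) -> np.ndarray:
            if not bound:
                return np.zeros(n)
            if sign > 0:
                return rng.uniform(0, bound, n)
            return _truncated_uniform(rng, -bound, 0.0, floor)

        dw = _signed_magnitudes(s_dw, config.dw_bound, w_floor)
        dh = _signed_magnitudes(s_dh, config.dh_bound, h_floor)
        al = s_al * rng.uniform(0, config.alpha_bound, n) if config.alpha_bound else np.zeros(n)
        tx = np.zeros(n)
        ty = np.zeros(n)
        if config.translation_bound:
            s_tx, s_ty = rng.choice((-1.0, 1.0)), rng.choice((-1.0, 1.0))
            tx = s_tx * rng.uniform(0, config.translation_bound, n)
            ty = s_ty * rng.uniform(0, config.translation_bound, n)
    for i, k in enumerate(slice_indices):
        out.append(SliceParams(int(k), float(dw[i]), float(dh[i]), float(al[i]),
                               float(tx[i]), float(ty[i])))
    return out


def sample_outplane_shift(
    config: AugmentationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Independent uniform draws of the superior/inferior boundary shift."""
    m = config.slice_shift_max
    if m == 0:
        return 0, 0
    choices = np.arange(-m, m + 1)
    return int(rng.choice(choices)), int(rng.choice(choices))


# --- mask transforms --------------------------------------------------------


def _transform_slice(
    sl: np.ndarray, spacing_xy: tuple[float, float], params: SliceParams
) -> np.ndarray:
    """Nearest-neighbour resample of one binary slice through the inverse of
    (rotation about centroid) ∘ (anisotropic scaling about centroid)."""
    idx = np.argwhere(sl)
    if idx.size == 0 or params.is_identity:
        return sl.copy()
    sx_mm, sy_mm = spacing_xy
    # tight bounding box in mm (voxel extents, not centre-to-centre)
    w = (idx[:, 0].max() - idx[:, 0].min() + 1) * sx_mm
    h = (idx[:, 1].max() - idx[:, 1].min() + 1) * sy_mm
    if w + params.dw <= 0 or h + params.dh <= 0:
        raise ValueError(
            f"slice {params.slice_index}: perturbed width/height not positive "
            f"(w={w:.2f}+{params.dw:.2f}, h={h:.2f}+{params.dh:.2f})"
        )
    scale_x = (w + params.dw) / w
    scale_y = (h + params.dh) / h
    params.applied_scale_x = scale_x
    params.applied_scale_y = scale_y
    centroid_idx = idx.mean(axis=0)
    c_mm = centroid_idx * np.array([sx_mm, sy_mm])

    a = math.radians(params.alpha)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    fwd = rot @ np.diag([scale_x, scale_y])  # scale then rotate, in mm
    inv_mm = np.linalg.inv(fwd)
    d = np.diag([sx_mm, sy_mm])
    inv_idx = np.linalg.inv(d) @ inv_mm @ d
    shift_idx = np.array([params.tx / sx_mm, params.ty / sy_mm])
    # input_index = inv_idx @ (output_index - centroid - shift) + centroid
    offset = centroid_idx - inv_idx @ (centroid_idx + shift_idx)
    out = ndimage.affine_transform(
        sl.astype(np.uint8), inv_idx, offset=offset, order=0,
        mode="constant", cval=0, output=np.uint8,
    )
    return out


def apply_inplane(mask: BinaryMask, params: list[SliceParams]) -> BinaryMask:
    """Apply per-slice in-plane perturbations; empty slices pass through."""
    by_slice = {p.slice_index: p for p in params}
    missing = set(mask.foreground_slices().tolist()) - set(by_slice)
    if missing:
        raise ValueError(f"missing SliceParams for in-ROI slices {sorted(missing)}")
    out = np.array(mask.data, copy=True)
    sp_xy = (mask.spacing[0], mask.spacing[1])
    for k, p in by_slice.items():
        if mask.data[:, :, k].any():
            out[:, :, k] = _transform_slice(mask.data[:, :, k], sp_xy, p)
    return mask.copy_with(out)


def apply_outplane(mask: BinaryMask, delta_sup: int, delta_inf: int) -> BinaryMask:
    """Shift the superior/inferior boundary-slice choice.

    ``delta = -1`` removes the boundary slice's foreground; ``+1`` replicates
    the boundary slice's contour into the adjacent empty slice. The superior
    boundary is the highest foreground slice index, the inferior the lowest.
    """
    fg = mask.foreground_slices()
    if len(fg) < 3:
        raise ValueError("out-plane perturbation needs a mask spanning >= 3 slices")
    k_inf, k_sup = int(fg[0]), int(fg[-1])
    out = np.array(mask.data, copy=True)
    nz = mask.shape[2]
    if delta_sup >= 1 and k_sup + delta_sup >= nz:
        raise ValueError("superior growth past the grid edge")
    if delta_inf >= 1 and k_inf - delta_inf < 0:
        raise ValueError("inferior growth past the grid edge")
    span_after = (k_sup + delta_sup) - (k_inf - delta_inf) + 1
    if span_after < 1:
        raise ValueError("out-plane shrink would empty the mask")
    for d in range(1, max(delta_sup, 0) + 1):
        out[:, :, k_sup + d] = mask.data[:, :, k_sup]
    for d in range(1, max(-delta_sup, 0) + 1):
        out[:, :, k_sup - d + 1] = 0
    for d in range(1, max(delta_inf, 0) + 1):
        out[:, :, k_inf - d] = mask.data[:, :, k_inf]
    for d in range(1, max(-delta_inf, 0) + 1):
        out[:, :, k_inf + d - 1] = 0
    return mask.copy_with(out)


def _slice_dims_mm(mask: BinaryMask, k: int) -> tuple[float, float]:
    """Tight bounding-box width/height (mm) of one axial slice's foreground."""
    idx = np.argwhere(mask.data[:, :, k])
    w = (idx[:, 0].max() - idx[:, 0].min() + 1) * mask.spacing[0]
    h = (idx[:, 1].max() - idx[:, 1].min() + 1) * mask.spacing[1]
    return float(w), float(h)


# --- top-level generator ----------------------------------------------------


def augment(mask: BinaryMask, config: AugmentationConfig) -> AugmentedMaskSet:
    """Generate ``config.n_contours`` perturbed masks from a ground truth.

    ``in_out_plane`` composes the out-plane boundary shift first, then the
    in-plane perturbation on the resulting slice extent. Out-plane shifts are
    always random; the bias setting applies to the in-plane component only.
    """
    rng = np.random.default_rng(config.seed)
    perturbed: list[BinaryMask] = []
    logs: list[ContourLog] = []
    for _ in range(config.n_contours):
        log = ContourLog()
        current = mask
        if config.scenario in ("out_plane", "in_out_plane"):
            log.delta_sup, log.delta_inf = sample_outplane_shift(config, rng)
            current = apply_outplane(current, log.delta_sup, log.delta_inf)
        if config.scenario in ("in_plane", "in_out_plane"):
            slices = current.foreground_slices()
            dims = {int(k): _slice_dims_mm(current, int(k)) for k in slices}
            log.slice_params = sample_inplane_params(
                config, slices, config.bias, rng, min_dims=dims
            )
            current = apply_inplane(current, log.slice_params)
        perturbed.append(current)
        logs.append(log)
    return AugmentedMaskSet(mask, perturbed, logs, config, config.seed)
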