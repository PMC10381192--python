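"""Synthetic prostate-scale mpMRI phantoms.

Generates irregular-ellipsoid masks and matching textured T2w-like volumes,
multi-b-value DWI stacks, and dynamic contrast-enhanced (DCE) series so that
the full perturbation/extraction/stability chain can run without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .core import BinaryMask, DynamicSeries, GeometryError, VolumeImage

#: default voxel spacings (mm) per synthetic sequence
DEFAULT_SPACINGS = {
    "t2w": (0.297, 0.297, 3.0),
    "adc": (1.25, 1.25, 3.0),
    "dce": (1.136, 1.136, 3.0),
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic prostate phantom.

    ``semi_axes`` are the ellipsoid half-lengths in mm; ``surface_irregularity``
    is the relative amplitude of a band-limited radial modulation in [0, 0.2].
    """

    semi_axes: tuple[float, float, float] = (22.5, 19.0, 20.0)
    surface_irregularity: float = 0.0
    spacing: tuple[float, float, float] = DEFAULT_SPACINGS["t2w"]
    grid_shape: tuple[int, int, int] | None = None
    dce_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 181.0, 10.0))
    b_values: tuple[float, ...] = (0.0, 1500.0, 2000.0)
    dce_time_to_peak: float = 75.0
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.semi_axes = tuple(float(a) for a in self.semi_axes)  # type: ignore[assignment]
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.dce_times = np.asarray(self.dce_times, dtype=float)
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.surface_irregularity <= 0.2:
            raise ValueError("surface_irregularity must lie in [0, 0.2]")
        if np.any(np.diff(self.dce_times) <= 0):
            raise ValueError("dce_times must be strictly increasing")
        if len(set(self.b_values)) < 2 or any(b < 0 for b in self.b_values):
            raise ValueError("need >= 2 distinct non-negative b-values")

    def default_grid_shape(self, spacing: tuple[float, float, float]) -> tuple[int, int, int]:
        """Smallest comfortable grid: ellipsoid + irregularity + 4-voxel margin."""
        margin = 1.0 + self.surface_irregularity
        return tuple(
            int(np.ceil(2 * a * margin / s)) + 8
            for a, s in zip(self.semi_axes, spacing)
        )  # type: ignore[return-value]


# --- shape ------------------------------------------------------------------

_SH_DEGREES = (2, 3, 4)  # band limit of the radial surface modulation


def _surface_coefficients(rng: np.random.Generator) -> list[np.ndarray]:
    """Random coefficients of the low-order spherical-harmonic modulation."""
    return [rng.standard_normal(2 * ell + 1) for ell in _SH_DEGREES]


def _radial_modulation(coeffs: list[np.ndarray], theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Band-limited real function on the sphere, normalised to max |f| = 1."""
    out = np.zeros_like(theta)
    for ell, c in zip(_SH_DEGREES, coeffs):
        for i, m in enumerate(range(-ell, ell + 1)):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                out += c[i] * np.sqrt(2) * y.imag
            elif m == 0:
                out += c[i] * y.real
            else:
                out += c[i] * np.sqrt(2) * y.real
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _voxelize(
    spec: PhantomSpec,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    coeffs: list[np.ndarray] | None,
) -> np.ndarray:
    a, b, c = spec.semi_axes
    center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    xs = [np.arange(n) * s - cc for n, s, cc in zip(shape, spacing, center)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    U, V, W = X / a, Y / b, Z / c
    rho = np.sqrt(U**2 + V**2 + W**2)
    limit = np.ones_like(rho)
    if coeffs is not None and spec.surface_irregularity > 0:
        theta = np.arccos(np.clip(W / np.where(rho > 0, rho, 1.0), -1, 1))
        phi = np.arctan2(V, U)
        limit = 1.0 + spec.surface_irregularity * _radial_modulation(coeffs, theta, phi)
    inside = rho <= limit
    margin = 1.0 + spec.surface_irregularity
    if (
        2 * a * margin > shape[0] * spacing[0]
        or 2 * b * margin > shape[1] * spacing[1]
        or 2 * c * margin > shape[2] * spacing[2]
    ):
        raise GeometryError("ellipsoid (plus irregularity margin) exceeds the grid")
    return inside.astype(np.uint8)


def generate_phantom_mask(spec: PhantomSpec) -> BinaryMask:
    """Voxelize the (optionally irregular) ellipsoid on the spec's grid.

    The output has a single 6-connected foreground component centred on the
    grid, and is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    coeffs = _surface_coefficients(rng) if spec.surface_irregularity > 0 else None
    shape = spec.grid_shape or spec.default_grid_shape(spec.spacing)
    arr = _voxelize(spec, spec.spacing, shape, coeffs)
    lab, n = ndimage.label(arr, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:  # star-shaped domains stay connected; guard anyway
        sizes = ndimage.sum_labels(arr, lab, index=np.arange(1, n + 1))
        arr = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return BinaryMask(arr, spec.spacing)


# --- intensities ------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-std smooth random texture."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return (f - f.mean()) / (f.std() + 1e-12)


def gamma_variate(t: np.ndarray, time_to_peak: float, shape: float = 2.0) -> np.ndarray:
    """Rise-then-decay enhancement curve, normalised to peak 1 at ``time_to_peak``."""
    tt = np.clip(np.asarray(t, dtype=float) / time_to_peak, 0, None)
    return tt**shape * np.exp(shape * (1.0 - tt))


@dataclass
class MpmriPhantom:
    """One synthetic subject: images and per-sequence masks on native grids.

    Sequence attributes are ``None`` when not requested at generation time.
    """

    masks: dict[str, BinaryMask]
    b_values: tuple[float, ...]
    t2w: VolumeImage | None = None
    dwi_stack: list[VolumeImage] | None = None
    dce: DynamicSeries | None = None
    adc_truth: VolumeImage | None = None


def generate_mpmri_phantom(
    spec: PhantomSpec,
    spacings: dict[str, tuple[float, float, float]] | None = None,
) -> MpmriPhantom:
    """Generate T2w / DWI / DCE volumes plus the shared ROI per sequence grid.

    ``spacings`` selects which sequences (keys ``t2w``/``adc``/``dce``) are
    generated and on what grids; defaults to all three. DWI follows
    ``S(b) = S0 * exp(-b * A)`` voxelwise with a smoothly varying ``A`` around
    1.2e-3 mm^2/s; DCE in-gland voxels follow a gamma-variate enhancement
    curve so wash-in and wash-out subtractions are both nonzero.
    """
    spacings = dict(DEFAULT_SPACINGS if spacings is None else spacings)
    rng = np.random.default_rng(spec.seed)
    coeffs = _surface_coefficients(rng) if spec.surface_irregularity > 0 else None

    masks: dict[str, BinaryMask] = {}
    for seq, sp in spacings.items():
        shape = spec.default_grid_shape(sp)
        masks[seq] = BinaryMask(_voxelize(spec, sp, shape, coeffs), sp)

    out = MpmriPhantom(masks=masks, b_values=spec.b_values)

    if "t2w" in masks:  # smooth texture, distinct in-gland vs background mean
        m = masks["t2w"]
        tex = _smooth_field(rng, m.shape, sigma_vox=3.0)
        t2_arr = 200.0 + 60.0 * tex + 300.0 * m.data
        if spec.noise_level > 0:
            t2_arr = t2_arr + spec.noise_level * 200.0 * rng.standard_normal(m.shape)
        out.t2w = VolumeImage(t2_arr, m.spacing)

    if "adc" in masks:  # mono-exponential DWI with spatially varying ADC
        md = masks["adc"]
        adc_field = 1.2e-3 * (1.0 + 0.25 * _smooth_field(rng, md.shape, sigma_vox=2.0))
        adc_field = np.clip(adc_field, 2e-4, None)
        s0 = 800.0 * (1.0 + 0.15 * _smooth_field(rng, md.shape, sigma_vox=2.0)) \
            + 200.0 * md.data
        s0 = np.clip(s0, 50.0, None)
        out.dwi_stack = []
        for b in spec.b_values:
            sig = s0 * np.exp(-b * adc_field)
            if spec.noise_level > 0:
                sig = np.clip(
                    sig + spec.noise_level * sig * rng.standard_normal(md.shape),
                    1e-3, None,
                )
            out.dwi_stack.append(VolumeImage(sig, md.spacing))
        out.adc_truth = VolumeImage(adc_field, md.spacing)

    if "dce" in masks:  # baseline + gamma-variate enhancement inside the gland
        mc = masks["dce"]
        base = 100.0 * (1.0 + 0.2 * _smooth_field(rng, mc.shape, sigma_vox=2.0))
        amp = 150.0 * (1.0 + 0.3 * _smooth_field(rng, mc.shape, sigma_vox=2.0)) * mc.data
        curve = gamma_variate(spec.dce_times, spec.dce_time_to_peak)
        frames = []
        for k in range(len(spec.dce_times)):
            fr = base + amp * curve[k]
            if spec.noise_level > 0:
                fr = fr + spec.noise_level * 20.0 * rng.standard_normal(mc.shape)
            frames.append(VolumeImage(fr, mc.spacing))
        out.dce = DynamicSeries(frames, spec.dce_times)

    return out
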