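"""Core grid-aware containers and NIfTI I/O.

Conventions used throughout the package:

* arrays are indexed ``(x, y, z)`` with the axial (cranio-caudal) direction on
  the **third** axis; slice index 0 is the inferior-most slice;
* all indexing is 0-based;
* world coordinates of voxel ``i`` along an axis are ``origin + i * spacing``
  (node convention), in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

AXIAL_AXIS = 2


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class GeometryError(ValueError):
    """A geometric precondition (shape fits grid, valid spacing, ...) failed."""


def _as_tuple3(values: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in values)
    if len(t) != 3:
        raise ValueError(f"expected 3 values, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A 3D scalar grid with physical voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "VolumeImage") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(np.asarray(data), self.spacing, self.origin)

    # --- NIfTI ---------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


@dataclass
class BinaryMask(VolumeImage):
    """A {0,1} grid sharing a :class:`VolumeImage` geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)

    def copy_with(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(data), self.spacing, self.origin)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.voxel_volume

    def foreground_slices(self) -> np.ndarray:
        """Indices of axial slices containing at least one foreground voxel."""
        return np.flatnonzero(self.data.any(axis=(0, 1)))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        vol = VolumeImage.load(path)
        return cls((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.spacing, vol.origin)


@dataclass
class DynamicSeries:
    """A temporally ordered stack of co-registered volumes (e.g. DCE frames)."""

    frames: list[VolumeImage]
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("one acquisition time per frame required")
        if len(self.frames) < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        first = self.frames[0]
        for fr in self.frames[1:]:
            first.require_same_grid(fr)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid(self) -> VolumeImage:
        return self.frames[0]

    def as_4d(self) -> np.ndarray:
        return np.stack([f.data for f in self.frames], axis=-1)

    def save(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write a 4D NIfTI plus a JSON sidecar holding acquisition times (s)."""
        img = nib.Nifti1Image(self.as_4d().astype(np.float32), self.grid.affine())
        nib.save(img, str(path))
        if sidecar is None:
            sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
        Path(sidecar).write_text(json.dumps({"times_s": self.times.tolist()}))

    @classmethod
    def load(cls, path: str | Path, sidecar: str | Path | None = None) -> "DynamicSeries":
        img = nib.load(str(path))
        if sidecar is None:
            sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
        times = np.asarray(json.loads(Path(sidecar).read_text())["times_s"], dtype=float)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        arr = np.asarray(img.dataobj, dtype=np.float64)
        frames = [VolumeImage(arr[..., t], spacing, origin) for t in range(arr.shape[-1])]
        return cls(frames, times)
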