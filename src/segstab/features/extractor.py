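"""Feature-extraction harness: 17 filter variants x 72 features = 1224.

Discretization (fixed bin width, default 5) is performed per filter variant on
the in-ROI voxels of the filtered image. Shape features are deliberately
absent: the per-pair feature count is 17 * (18 + 22 + 16 + 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import BinaryMask, VolumeImage
from .discretize import discretize
from .filters import filter_bank
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    glcm_features,
    glrlm_features,
    glszm_features,
)

FAMILIES = ("firstorder", "glcm", "glrlm", "glszm")
FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
}


@dataclass
class ExtractionConfig:
    bin_width: float = 5.0
    log_sigmas: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    families: tuple[str, ...] = FAMILIES
    filters: tuple[str, ...] | None = None  # None = all 17 variants

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")


@dataclass(frozen=True)
class FeatureKey:
    """Identifies one feature value: (sequence, filter, family, name)."""

    sequence: str
    filter: str
    family: str
    name: str

    def __str__(self) -> str:
        return f"{self.sequence}|{self.filter}|{self.family}|{self.name}"

    @classmethod
    def parse(cls, s: str) -> "FeatureKey":
        seq, flt, fam, name = s.split("|")
        return cls(seq, flt, fam, name)


def _label_volume(img: VolumeImage, mask: BinaryMask, bin_width: float):
    """Discretized grey-level volume (0 outside ROI) plus the level count."""
    roi = mask.data > 0
    values = np.asarray(img.data, dtype=float)[roi]
    labels_flat, n_levels = discretize(values, bin_width)
    labels = np.zeros(img.shape, dtype=np.int64)
    labels[roi] = labels_flat
    # texture matrices only see in-ROI voxels; crop to the ROI bounding box
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(roi)
    )
    return labels[bbox], n_levels


def extract_family(
    img: VolumeImage,
    mask: BinaryMask,
    family: str,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """One family's feature vector for a single image/mask pair."""
    config = config or ExtractionConfig()
    img.require_same_grid(mask)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    roi = mask.data > 0
    if not roi.any():
        raise ValueError("empty ROI")
    if family == "firstorder":
        values = np.asarray(img.data, dtype=float)[roi]
        return firstorder_features(values, img.voxel_volume, config.bin_width)
    labels, n_levels = _label_volume(img, mask, config.bin_width)
    if family == "glcm":
        return glcm_features(labels, n_levels)
    if family == "glrlm":
        return glrlm_features(labels, n_levels)
    return glszm_features(labels, n_levels)


def extract_all(
    img: VolumeImage,
    mask: BinaryMask,
    config: ExtractionConfig | None = None,
    sequence: str = "image",
) -> dict[FeatureKey, float]:
    """All configured (filter, family, feature) values for one rater.

    With the default configuration this emits exactly 17 * 72 = 1224 values
    in a stable key order.
    """
    config = config or ExtractionConfig()
    img.require_same_grid(mask)
    variants = filter_bank(img, config.log_sigmas)
    if config.filters is not None:
        variants = {k: v for k, v in variants.items() if k in config.filters}
    out: dict[FeatureKey, float] = {}
    for flt_label, variant in variants.items():
        for family in config.families:
            feats = extract_family(variant, mask, family, config)
            for name in FAMILY_NAMES[family]:
                out[FeatureKey(sequence, flt_label, family, name)] = feats[name]
    return out
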