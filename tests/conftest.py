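import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from segstab.core import BinaryMask, VolumeImage
from segstab.phantom import PhantomSpec, generate_mpmri_phantom, generate_phantom_mask
from segstab.preprocess import (
    PreprocessConfig,
    compute_adc_map,
    normalize_roi,
    resample_image,
    resample_mask,
)


@pytest.fixture(scope="session")
def adc_spacing():
    return (1.25, 1.25, 3.0)


@pytest.fixture(scope="session")
def default_mask(adc_spacing):
    """Irregular prostate-scale mask on an ADC-like grid."""
    spec = PhantomSpec(spacing=adc_spacing, surface_irregularity=0.1, seed=42)
    return generate_phantom_mask(spec)


@pytest.fixture(scope="session")
def normalized_pair(adc_spacing):
    """A preprocessed (normalized 2 mm image, resampled mask) pair."""
    spec = PhantomSpec(spacing=adc_spacing, surface_irregularity=0.1, seed=7)
    ph = generate_mpmri_phantom(spec, {"adc": adc_spacing})
    adc = compute_adc_map(ph.dwi_stack, ph.b_values)
    cfg = PreprocessConfig()
    img = resample_image(adc, cfg)
    mask = resample_mask(ph.masks["adc"], cfg)
    return normalize_roi(img, mask, cfg), mask


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), spacing)


def make_image(arr, spacing=(1.0, 1.0, 1.0)):
    return VolumeImage(np.asarray(arr, dtype=float), spacing)


@pytest.fixture
def block_mask():
    """A 4x4x6 block inside a 12x12x12 grid, spanning slices 3..8."""
    arr = np.zeros((12, 12, 12), dtype=np.uint8)
    arr[4:8, 4:8, 3:9] = 1
    return make_mask(arr)
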