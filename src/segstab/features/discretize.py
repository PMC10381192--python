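"""Fixed-bin-width grey-level discretization anchored at the ROI minimum."""

from __future__ import annotations

import numpy as np


def discretize(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Bin ROI intensities at a constant width.

    Labels are ``floor((x - min) / width) + 1``; the number of bins is
    ``ceil((max - min) / width)`` (at least 1), and a value sitting exactly on
    the top edge is assigned to the last bin — a ROI spanning exactly 0..600
    at width 5 therefore yields 120 bins. Returns ``(labels, n_bins)`` where
    ``n_bins`` is the maximum label.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(v.min()), float(v.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    labels = np.floor((v - lo) / bin_width).astype(np.int64) + 1
    labels = np.clip(labels, 1, n_bins)
    return labels, n_bins
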