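"""Gray-level discretization: the prerequisite of every texture matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedImage:
    """Integer gray levels 1..n_levels on the in-mask voxels (0 elsewhere)."""

    levels: np.ndarray     # int array, 0 outside mask
    mask: np.ndarray       # bool
    n_levels: int
    bin_edges: np.ndarray

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedImage:
    """Equal-width binning over the [min, max] range of in-mask intensities.

    A constant region collapses to a single level. Levels are 1-based;
    voxels outside the mask carry level 0.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        return DiscretizedImage(levels, mask, 1, np.array([lo, hi]))
    width = (hi - lo) / n_bins
    lev = np.floor((values[mask] - lo) / width).astype(np.int64) + 1
    np.clip(lev, 1, n_bins, out=lev)
    levels[mask] = lev
    edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedImage(levels, mask, int(n_bins), edges)
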