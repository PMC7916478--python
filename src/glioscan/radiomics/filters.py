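"""LoG and wavelet filter banks applied ahead of feature computation."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from ..image import ImageVolume


@dataclass
class FilterBankConfig:
    """Derived-image inventory: original + LoG scales + wavelet sub-bands."""

    log_sigmas_mm: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    wavelet: bool = True
    wavelet_name: str = "coif1"
    n_bins: int = 32
    include_shape: bool = True
    texture_classes: tuple[str, ...] = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")


def log_filter(img: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian-of-Gaussian at physical scale `sigma_mm` (converted to
    voxels per axis via the spacing). Linear; annihilates constants and
    affine ramps in the interior."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if sigma_mm < max(img.spacing_mm) / 2.0:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm under-resolved for voxel size {img.spacing_mm}"
        )
    sigma_vox = [sigma_mm / s for s in img.spacing_mm]
    # truncate=8: the truncated second-derivative kernel then sums to ~0,
    # so constants and affine ramps are annihilated to near machine precision
    out = ndimage.gaussian_laplace(img.values, sigma=sigma_vox, mode="nearest",
                                   truncate=8.0)
    return img.with_values(out)


def _wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(name)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    # normalize to unit DC gain on the low-pass so constants pass unchanged
    scale = lo.sum()
    return lo / scale, hi / scale


def wavelet_decompose(img: ImageVolume, wavelet: str = "coif1") -> dict[str, ImageVolume]:
    """Single-level undecimated separable 3D decomposition.

    Returns the 8 sub-bands keyed 'LLL'..'HHH'; letter i selects the low- or
    high-pass filter along array axis i (x, y, z). Sub-bands keep the input
    shape (no decimation). Symmetric boundary handling.
    """
    lo, hi = _wavelet_filters(wavelet)
    bank = {"L": lo, "H": hi}
    out: dict[str, ImageVolume] = {}
    for label in ("".join(t) for t in itertools.product("LH", repeat=3)):
        vals = img.values
        for axis, letter in enumerate(label):
            vals = ndimage.convolve1d(vals, bank[letter], axis=axis, mode="reflect")
        out[label] = img.with_values(vals)
    return out
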