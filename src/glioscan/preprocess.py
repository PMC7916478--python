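"""Geometric and intensity normalization of heterogeneous MR acquisitions.

Pipeline order: resample to a common grid, N4 bias-field correction, global
histogram equalization, Z-score standardization with parameters estimated on
the training cohort and *transferred* (frozen) to validation. The published
transfer parameters of the study this mirrors (T1 mu=0.1904, sigma=0.2313;
T2 mu=0.2009, sigma=0.2448) can be supplied as overrides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .image import ImageVolume

# in-plane / through-plane resampling target of the clinical study (mm)
DEFAULT_TARGET_SPACING = (0.449, 0.449, 5.5)

# published frozen Z-score transfer parameters, usable as config overrides
PUBLISHED_ZSCORE = {"T1Gd": (0.1904, 0.2313), "T2": (0.2009, 0.2448)}


@dataclass
class ZScoreParams:
    """Frozen standardization parameters, estimated on training only."""

    mu: float
    sigma: float
    modality: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")


def resample_volume(
    img: ImageVolume,
    target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
) -> ImageVolume:
    """Resample onto `target_spacing`, preserving the physical extent.

    In-plane interpolation is cubic-spline (4x4 support, reproduces affine
    intensities exactly); through-plane interpolation is linear — thick
    slices make cubic overshoot risky. Single-slice inputs keep their
    through-plane geometry unchanged.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    vals = img.values
    old_sp = img.spacing_mm
    out_sp = list(target_spacing)

    # physical extent is preserved: new_n * new_s = old_n * old_s
    def _axis_coords(n_old, s_old, s_new):
        n_new = max(1, int(round(n_old * s_old / s_new)))
        # sample centers of the new grid expressed in old-grid index units
        return (np.arange(n_new) * s_new) / s_old, n_new

    cx, nx = _axis_coords(vals.shape[0], old_sp[0], out_sp[0])
    cy, ny = _axis_coords(vals.shape[1], old_sp[1], out_sp[1])

    if (nx, ny) == vals.shape[:2] and np.allclose(old_sp[:2], out_sp[:2]):
        inplane = vals
    else:
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        inplane = np.empty((nx, ny, vals.shape[2]))
        for k in range(vals.shape[2]):
            inplane[:, :, k] = ndimage.map_coordinates(
                vals[:, :, k], [gx, gy], order=3, mode="nearest"
            )

    if vals.shape[2] == 1:
        out = inplane
        out_sp[2] = old_sp[2]
    else:
        cz, nz = _axis_coords(vals.shape[2], old_sp[2], out_sp[2])
        if nz == vals.shape[2] and np.isclose(old_sp[2], out_sp[2]):
            out = inplane
        else:
            gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), cz, indexing="ij")
            out = ndimage.map_coordinates(inplane, [gx, gy, gz], order=1, mode="nearest")
    return ImageVolume(out, tuple(out_sp), img.modality)


def resample_mask(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto the target grid
    (same physical extent convention as `resample_volume`)."""
    img = ImageVolume(mask.astype(np.float64), spacing_mm)
    coords = []
    shape = []
    for n_old, s_old, s_new in zip(mask.shape, spacing_mm, target_spacing):
        n_new = max(1, int(round(n_old * s_old / s_new)))
        coords.append((np.arange(n_new) * s_new) / s_old)
        shape.append(n_new)
    grids = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(mask.astype(np.float64), grids, order=0, mode="nearest")
    return out > 0.5


def spacing_mode(spacings: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Modal spacing of a cohort — the resampling reference that minimizes
    the number of resampled images."""
    arr = np.round(np.asarray(spacings, dtype=float), 6)
    out = []
    for ax in range(3):
        vals, counts = np.unique(arr[:, ax], return_counts=True)
        out.append(float(vals[np.argmax(counts)]))
    return tuple(out)


def n4_bias_correct(
    img: ImageVolume,
    mask: np.ndarray | None = None,
    shrink: int = 2,
    max_iterations: tuple[int, ...] = (30, 30),
) -> tuple[ImageVolume, dict]:
    """Divide out a smooth multiplicative bias field estimated by N4.

    Returns the corrected image and a provenance dict (shift applied to make
    the image positive, convergence flag). Non-positive images are shifted,
    corrected, and shifted back conceptually by rescaling only the
    multiplicative part.
    """
    vals = img.values
    shift = 0.0
    minv = vals.min()
    if minv <= 0:
        shift = -minv + 1.0
    work = vals + shift

    if mask is not None and not np.asarray(mask).any():
        raise ValueError("mask is empty")
    ref = work if mask is None else work[mask]
    if ref.std() <= 1e-12 * max(1.0, abs(ref.mean())):
        # constant image: the multiplicative field is exactly 1
        return img, {"shift": shift, "converged": True, "constant_input": True}

    it = sitk.GetImageFromArray(np.ascontiguousarray(work.T))  # sitk is (z,y,x)
    it.SetSpacing(tuple(float(s) for s in img.spacing_mm))
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)  # estimate the field everywhere
    if not mask.any():
        raise ValueError("mask is empty")
    mk = sitk.GetImageFromArray(np.ascontiguousarray(mask.T.astype(np.uint8)))
    mk.SetSpacing(it.GetSpacing())

    small = sitk.Shrink(it, [shrink] * 3) if shrink > 1 else it
    small_mk = sitk.Shrink(mk, [shrink] * 3) if shrink > 1 else mk
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations(list(max_iterations))
    converged = True
    try:
        corrector.Execute(small, small_mk)
        log_field = corrector.GetLogBiasFieldAsImage(it)
        field = np.exp(sitk.GetArrayFromImage(log_field)).T
    except RuntimeError as exc:  # non-convergence: return input, flagged
        warnings.warn(f"N4 did not converge ({exc}); returning input unchanged")
        return img, {"shift": shift, "converged": False}
    field = np.clip(field, 1e-6, None)
    corrected = work / field - shift
    return img.with_values(corrected), {"shift": shift, "converged": converged}


def equalize_histogram(img: ImageVolume) -> ImageVolume:
    """Global histogram equalization: map each voxel to the empirical CDF
    P(X <= x) of the volume's intensities. Monotone, range [0, 1]; a
    constant image maps to the constant 1."""
    vals = img.values
    flat = vals.ravel()
    uniq, counts = np.unique(flat, return_counts=True)
    cdf = np.cumsum(counts) / flat.size
    out = cdf[np.searchsorted(uniq, flat)].reshape(vals.shape)
    return img.with_values(out)


def estimate_zscore_params(images: list[ImageVolume]) -> ZScoreParams:
    """Pooled mean/sd of all voxel intensities of one modality's training
    images (after the preceding pipeline steps)."""
    if not images:
        raise ValueError("need at least one training image")
    modality = images[0].modality
    pooled = np.concatenate([im.values.ravel() for im in images])
    sigma = float(pooled.std())
    if sigma == 0:
        raise ValueError("pooled variance is zero; cannot standardize")
    return ZScoreParams(mu=float(pooled.mean()), sigma=sigma, modality=modality)


def apply_zscore(img: ImageVolume, params: ZScoreParams) -> ImageVolume:
    return img.with_values((img.values - params.mu) / params.sigma)


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] | None = DEFAULT_TARGET_SPACING
    bias_correct: bool = True
    equalize: bool = True
    zscore: bool = True
    n4_shrink: int = 2
    n4_iterations: tuple[int, ...] = (30, 30)


def preprocess_pipeline(
    img: ImageVolume,
    params: ZScoreParams | None,
    config: PreprocessConfig = PreprocessConfig(),
    mask: np.ndarray | None = None,
) -> tuple[ImageVolume, dict]:
    """Resample -> N4 -> equalize -> Z-score, in that order, with a
    per-image provenance log. Steps are individually toggleable."""
    log: dict = {"modality": img.modality, "steps": []}
    out = img
    if config.target_spacing is not None:
        out = resample_volume(out, config.target_spacing)
        log["steps"].append({"step": "resample", "target_spacing": list(config.target_spacing)})
    if config.bias_correct:
        out, n4log = n4_bias_correct(out, mask=None, shrink=config.n4_shrink,
                                     max_iterations=config.n4_iterations)
        log["steps"].append({"step": "n4", **n4log})
    if config.equalize:
        out = equalize_histogram(out)
        log["steps"].append({"step": "equalize"})
    if config.zscore:
        if params is None:
            raise ValueError("Z-score step enabled but no ZScoreParams provided")
        out = apply_zscore(out, params)
        log["steps"].append({"step": "zscore", "mu": params.mu, "sigma": params.sigma})
    return out, log
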