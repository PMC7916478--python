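"""3D image container and NIfTI I/O.

Axis convention: array axes (0, 1, 2) = (x, y, z); axes 0-1 are in-plane,
axis 2 is the slice direction. Spacing is physical voxel size in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

Modality = str  # "T1Gd" | "T2"


@dataclass
class ImageVolume:
    """A 3D scalar grid with per-axis spacing (mm) and a modality tag."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: Modality = "T1Gd"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def save_nifti(path: str | Path, img: ImageVolume) -> None:
    affine = np.diag(list(img.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(img.values.astype(np.float64), affine), str(path))


def save_mask_nifti(path: str | Path, mask: np.ndarray, spacing_mm) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_nifti(path: str | Path, modality: Modality = "T1Gd") -> ImageVolume:
    im = nib.load(str(path))
    spacing = tuple(float(z) for z in im.header.get_zooms()[:3])
    return ImageVolume(np.asarray(im.dataobj, dtype=np.float64), spacing, modality)


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    im = nib.load(str(path))
    spacing = tuple(float(z) for z in im.header.get_zooms()[:3])
    return np.asarray(im.dataobj) > 0.5, spacing
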