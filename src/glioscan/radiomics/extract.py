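"""Per-patient feature extraction across modalities, filters and classes.

Feature ids follow the ``{modality}_{filter}_{class}_{name}`` grammar, e.g.
``T2_log.sigma.3.0.mm.3D_glszm_LargeAreaLowGrayLevelEmphasis`` or
``T1_wavelet.HHH_firstorder_Median``. Shape features are computed once per
modality on the original mask geometry. Undefined features are recorded
with a reason, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..image import ImageVolume
from .discretize import discretize
from .filters import FilterBankConfig, log_filter, wavelet_decompose
from .firstorder import first_order_features
from .shape import shape_features
from .texture import texture_matrices, texture_features


@dataclass
class FeatureExtraction:
    values: dict[str, float]
    undefined: dict[str, str]
    manifest: list[dict]

    def series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, name=name, dtype=float)


def derived_images(img: ImageVolume, config: FilterBankConfig) -> dict[str, ImageVolume]:
    """The filter-bank inventory: original + one image per LoG scale + the
    8 wavelet sub-bands."""
    out = {"original": img}
    for s in config.log_sigmas_mm:
        out[f"log.sigma.{s:.1f}.mm.3D"] = log_filter(img, s)
    if config.wavelet:
        for label, sub in wavelet_decompose(img, config.wavelet_name).items():
            out[f"wavelet.{label}"] = sub
    return out


def _bbox_crop(values: np.ndarray, mask: np.ndarray, margin: int = 0):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_features(
    t1: ImageVolume,
    t2: ImageVolume,
    t1_mask: np.ndarray,
    t2_mask: np.ndarray,
    config: FilterBankConfig = FilterBankConfig(),
) -> FeatureExtraction:
    values: dict[str, float] = {}
    undefined: dict[str, str] = {}
    manifest: list[dict] = []

    for modality, img, mask in [("T1", t1, t1_mask), ("T2", t2, t2_mask)]:
        if not mask.any():
            raise ValueError(f"{modality} mask is empty")
        if config.include_shape:
            for name, val in shape_features(mask, img.spacing_mm).items():
                fid = f"{modality}_original_shape_{name}"
                values[fid] = val
                manifest.append({"id": fid, "modality": modality,
                                 "filter": "original", "class": "shape", "name": name})
        for filt, der in derived_images(img, config).items():
            vals, msk = _bbox_crop(der.values, mask)
            fo, fo_undef = first_order_features(
                vals, msk, n_bins=config.n_bins, voxel_volume=img.voxel_volume_mm3
            )
            for name, val in fo.items():
                fid = f"{modality}_{filt}_firstorder_{name}"
                values[fid] = val
                manifest.append({"id": fid, "modality": modality, "filter": filt,
                                 "class": "firstorder", "name": name})
            for name, reason in fo_undef.items():
                undefined[f"{modality}_{filt}_firstorder_{name}"] = reason
            if config.texture_classes:
                dimg = discretize(vals, msk, n_bins=config.n_bins)
                mats = texture_matrices(dimg)
                tf, tf_undef = texture_features(mats)
                for key, val in tf.items():
                    cls, name = key.split("_", 1)
                    if cls not in config.texture_classes:
                        continue
                    fid = f"{modality}_{filt}_{cls}_{name}"
                    values[fid] = val
                    manifest.append({"id": fid, "modality": modality, "filter": filt,
                                     "class": cls, "name": name})
                for key, reason in tf_undef.items():
                    cls, name = key.split("_", 1)
                    if cls in config.texture_classes:
                        undefined[f"{modality}_{filt}_{cls}_{name}"] = reason
    return FeatureExtraction(values=values, undefined=undefined, manifest=manifest)


def extract_cohort(patients_volumes, config: FilterBankConfig = FilterBankConfig()) -> pd.DataFrame:
    """Wide patient x feature table from an iterable of
    ``(patient_id, t1, t2, t1_mask, t2_mask)`` tuples."""
    rows = {}
    for pid, t1, t2, m1, m2 in patients_volumes:
        rows[pid] = extract_features(t1, t2, m1, m2, config).values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
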