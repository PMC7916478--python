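"""First-order (intensity histogram) statistics over the in-mask voxels."""

from __future__ import annotations

import numpy as np

from .discretize import discretize


def first_order_features(
    values: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    voxel_volume: float = 1.0,
) -> tuple[dict[str, float], dict[str, str]]:
    """Returns (features, undefined) where `undefined` maps a feature name
    to the reason it could not be computed (e.g. dispersion statistics on a
    single-voxel mask). Percentiles use the linear-interpolation convention;
    entropies are base 2 over the equal-width discretized histogram."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(values, dtype=np.float64)[mask]
    n = x.size
    feats: dict[str, float] = {}
    undefined: dict[str, str] = {}

    feats["Energy"] = float(np.sum(x**2))
    feats["TotalEnergy"] = float(voxel_volume * np.sum(x**2))
    feats["Minimum"] = float(x.min())
    feats["Maximum"] = float(x.max())
    feats["Range"] = float(x.max() - x.min())
    feats["Mean"] = float(x.mean())
    feats["Median"] = float(np.median(x))
    feats["10Percentile"] = float(np.percentile(x, 10))
    feats["90Percentile"] = float(np.percentile(x, 90))
    feats["InterquartileRange"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    feats["RootMeanSquared"] = float(np.sqrt(np.mean(x**2)))
    feats["MeanAbsoluteDeviation"] = float(np.mean(np.abs(x - x.mean())))

    lo, hi = np.percentile(x, [10, 90])
    robust = x[(x >= lo) & (x <= hi)]
    feats["RobustMeanAbsoluteDeviation"] = float(np.mean(np.abs(robust - robust.mean())))

    var = float(np.mean((x - x.mean()) ** 2))
    feats["Variance"] = var
    if n < 2 or var == 0:
        reason = "single voxel" if n < 2 else "zero variance"
        for name in ("Skewness", "Kurtosis"):
            undefined[name] = reason
    else:
        m2 = var
        m3 = float(np.mean((x - x.mean()) ** 3))
        m4 = float(np.mean((x - x.mean()) ** 4))
        feats["Skewness"] = m3 / m2**1.5
        feats["Kurtosis"] = m4 / m2**2  # Pearson convention (not excess)

    # histogram statistics over the discretized in-mask intensities
    d = discretize(np.asarray(values, dtype=np.float64), mask, n_bins=max(n_bins, 2))
    counts = np.bincount(d.in_mask_levels, minlength=d.n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    feats["Uniformity"] = float(np.sum(p**2))
    feats["Entropy"] = float(-np.sum(nz * np.log2(nz)))
    return feats, undefined
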