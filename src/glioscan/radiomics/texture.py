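"""Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their features.

All builders are dimension-agnostic (2D slices or 3D volumes). Conventions:

* GLCM: distance 1, the 13 unique 3D directions (4 in 2D), symmetric,
  per-direction matrices retained; features are computed per direction and
  angle-averaged.
* GLRLM: runs of equal gray level along the same 13 directions; a voxel
  outside the mask breaks the run; per-direction feature values averaged.
* GLSZM: connected zones of equal gray level under full (26 / 8)
  connectivity.
* GLDM: dependence = number of neighbours (full connectivity) whose level
  differs by at most alpha (default 0) from the centre, plus one for the
  centre itself.
* NGTDM: per-level sums of |level - mean of valid in-mask neighbours|.

Formulas follow the standard radiomics reference definitions; entropies are
base 2. Degenerate statistics (e.g. GLCM Correlation with a single gray
level) are reported as undefined, never as NaN.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedImage

_EPS_FREE = True  # entropies sum over positive-probability cells only


def direction_offsets(ndim: int) -> list[tuple[int, ...]]:
    """Unique (modulo sign) nonzero offsets in {-1,0,1}^ndim: 13 in 3D, 4 in 2D."""
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        first_nonzero = next(o for o in off if o != 0)
        if first_nonzero > 0:
            offsets.append(off)
    return offsets


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    return [
        off
        for off in itertools.product((-1, 0, 1), repeat=ndim)
        if any(o != 0 for o in off)
    ]


def _shift_slices(off):
    src, dst = [], []
    for o in off:
        if o > 0:
            src.append(slice(o, None)); dst.append(slice(None, -o))
        elif o < 0:
            src.append(slice(None, o)); dst.append(slice(-o, None))
        else:
            src.append(slice(None)); dst.append(slice(None))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# matrix builders
# --------------------------------------------------------------------------

def glcm_matrix(dimg: DiscretizedImage) -> np.ndarray:
    """Stack of symmetric, normalized co-occurrence matrices, one per
    direction; shape (n_directions, Ng, Ng)."""
    levels, mask, ng = dimg.levels, dimg.mask, dimg.n_levels
    dirs = direction_offsets(levels.ndim)
    out = np.zeros((len(dirs), ng, ng))
    for d, off in enumerate(dirs):
        src, dst = _shift_slices(off)
        valid = mask[src] & mask[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize
        total = counts.sum()
        if total > 0:
            counts /= total
        out[d] = counts
    return out


def glrlm_matrix(dimg: DiscretizedImage) -> np.ndarray:
    """Stack of run-length count matrices P(level, run_length), one per
    direction; shape (n_directions, Ng, max_run_length)."""
    levels, mask, ng = dimg.levels, dimg.mask, dimg.n_levels
    ndim = levels.ndim
    dirs = direction_offsets(ndim)
    coords = np.argwhere(np.ones_like(mask, dtype=bool))
    lev_flat = levels.reshape(-1)
    msk_flat = mask.reshape(-1)
    max_len = max(levels.shape)
    out = np.zeros((len(dirs), ng, max_len))
    for d, off in enumerate(dirs):
        o = np.asarray(off)
        step = int(o @ o)
        t = coords @ o
        # points on one line share key = p*|d|^2 - (p.d) d
        key = coords * step - t[:, None] * o[None, :]
        order = np.lexsort((t,) + tuple(key[:, k] for k in range(ndim - 1, -1, -1)))
        ks, ts = key[order], t[order]
        lv, mk = lev_flat[order], msk_flat[order]
        same_line = np.all(ks[1:] == ks[:-1], axis=1) & (ts[1:] - ts[:-1] == step)
        cont = same_line & mk[1:] & mk[:-1] & (lv[1:] == lv[:-1])
        cont_ext = np.concatenate((cont, [False]))  # link j: voxel j continues to j+1
        # run starts: in-mask voxel not continued from the previous position
        starts = np.flatnonzero(mk & ~np.concatenate(([False], cont)))
        run_breaks = np.flatnonzero(~cont_ext)
        run_ends = run_breaks[np.searchsorted(run_breaks, starts)]
        lengths = run_ends - starts + 1
        np.add.at(out[d], (lv[starts] - 1, lengths - 1), 1.0)
    return out


def glszm_matrix(dimg: DiscretizedImage) -> np.ndarray:
    """Zone-size count matrix P(level, zone_size); shape (Ng, max_size)."""
    levels, mask, ng = dimg.levels, dimg.mask, dimg.n_levels
    structure = np.ones((3,) * levels.ndim, dtype=int)
    n_in = int(mask.sum())
    out = np.zeros((ng, n_in))
    for g in range(1, ng + 1):
        region = (levels == g) & mask
        if not region.any():
            continue
        lab, nlab = ndimage.label(region, structure=structure)
        sizes = np.bincount(lab.reshape(-1))[1:]
        for s in sizes:
            out[g - 1, s - 1] += 1
    # trim trailing empty size columns (keep at least one)
    nz = np.nonzero(out.sum(axis=0))[0]
    last = nz[-1] if nz.size else 0
    return out[:, : last + 1]


def gldm_matrix(dimg: DiscretizedImage, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P(level, dependence); dependence = number of
    full-connectivity neighbours with |level difference| <= alpha, plus one
    for the centre voxel. Shape (Ng, max_dependence)."""
    levels, mask, ng = dimg.levels, dimg.mask, dimg.n_levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _neighbor_offsets(levels.ndim):
        src, dst = _shift_slices(off)
        ok = mask[dst] & mask[src] & (np.abs(levels[dst] - levels[src]) <= alpha)
        dep[dst] += ok
    dep_in = dep[mask] + 1  # centre counts itself
    lev_in = levels[mask]
    max_dep = int(dep_in.max())
    out = np.zeros((ng, max_dep))
    np.add.at(out, (lev_in - 1, dep_in - 1), 1.0)
    return out


def ngtdm_matrix(dimg: DiscretizedImage) -> tuple[np.ndarray, np.ndarray]:
    """Returns (n_i, s_i): per-level voxel counts and summed absolute
    differences from the mean of valid in-mask neighbours. Voxels with no
    in-mask neighbour are excluded."""
    levels, mask, ng = dimg.levels, dimg.mask, dimg.n_levels
    vals = np.where(mask, levels.astype(np.float64), 0.0)
    cnt = np.zeros(levels.shape)
    ssum = np.zeros(levels.shape)
    for off in _neighbor_offsets(levels.ndim):
        src, dst = _shift_slices(off)
        ssum[dst] += np.where(mask[src], vals[src], 0.0)
        cnt[dst] += mask[src]
    valid = mask & (cnt > 0)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(levels[valid] - ssum[valid] / cnt[valid])
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = levels[valid]
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diff[valid])
    return n_i, s_i


def texture_matrices(dimg: DiscretizedImage, alpha: int = 0) -> dict:
    return {
        "glcm": glcm_matrix(dimg),
        "glrlm": glrlm_matrix(dimg),
        "glszm": glszm_matrix(dimg),
        "gldm": gldm_matrix(dimg, alpha=alpha),
        "ngtdm": ngtdm_matrix(dimg),
        "n_voxels": int(dimg.mask.sum()),
    }


# --------------------------------------------------------------------------
# feature evaluation
# --------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _glcm_single(p: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    ux = float(np.sum(i * px))
    sig2 = float(np.sum(px * (i - ux) ** 2))
    feats: dict[str, float] = {}
    undef: dict[str, str] = {}

    feats["Autocorrelation"] = float(np.sum(p * I * J))
    feats["JointAverage"] = ux
    for name, power in [("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)]:
        feats[name] = float(np.sum(p * (I + J - 2 * ux) ** power))
    feats["Contrast"] = float(np.sum(p * (I - J) ** 2))
    if sig2 > 0:
        feats["Correlation"] = float((np.sum(p * I * J) - ux * ux) / sig2)
    else:
        undef["Correlation"] = "single gray level (zero marginal variance)"

    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])
    da = float(np.sum(k_diff * p_diff))
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = _entropy(p_diff)
    feats["DifferenceVariance"] = float(np.sum(p_diff * (k_diff - da) ** 2))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])
    feats["SumAverage"] = float(np.sum(k_sum * p_sum))
    feats["SumEntropy"] = _entropy(p_sum)
    feats["SumSquares"] = float(np.sum(p * (I - ux) ** 2))

    feats["JointEnergy"] = float(np.sum(p**2))
    feats["JointEntropy"] = _entropy(p)
    feats["Id"] = float(np.sum(p / (1.0 + np.abs(I - J))))
    feats["Idm"] = float(np.sum(p / (1.0 + (I - J) ** 2)))
    off = I != J
    feats["InverseVariance"] = float(np.sum(p[off] / (I - J)[off] ** 2))
    feats["MaximumProbability"] = float(p.max())
    return feats, undef


def glcm_features(stack: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    """Angle-averaged features: per-direction values, then the mean."""
    per_dir = [_glcm_single(stack[d]) for d in range(stack.shape[0])]
    names = set().union(*(f for f, _ in per_dir)) | set().union(*(u for _, u in per_dir))
    feats, undef = {}, {}
    for name in names:
        if any(name in u for _, u in per_dir):
            undef[name] = next(u[name] for _, u in per_dir if name in u)
        else:
            feats[name] = float(np.mean([f[name] for f, _ in per_dir]))
    return feats, undef


def _run_type_features(P: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared skeleton of GLRLM (kind='Run') and GLSZM (kind='Area'/'Zone')
    features: P(i, s) with gray level i and run length / zone size s."""
    ng, ns = P.shape
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, ns + 1)[None, :]
    N = P.sum()
    p = P / N
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per size
    f: dict[str, float] = {}
    if kind == "Run":
        small, large, sz = "ShortRunEmphasis", "LongRunEmphasis", "Run"
        f["RunPercentage"] = float(N / n_voxels)
    else:
        small, large, sz = "SmallAreaEmphasis", "LargeAreaEmphasis", "Zone"
        f["ZonePercentage"] = float(N / n_voxels)
    f[small] = float(np.sum(P / s**2) / N)
    f[large] = float(np.sum(P * s**2) / N)
    f["GrayLevelNonUniformity"] = float(np.sum(pg**2) / N)
    f["GrayLevelNonUniformityNormalized"] = float(np.sum(pg**2) / N**2)
    f[f"{sz}LengthNonUniformity" if kind == "Run" else "SizeZoneNonUniformity"] = float(
        np.sum(ps**2) / N
    )
    f[f"{sz}LengthNonUniformityNormalized" if kind == "Run" else "SizeZoneNonUniformityNormalized"] = float(
        np.sum(ps**2) / N**2
    )
    mu_g = float(np.sum(p * i))
    f["GrayLevelVariance"] = float(np.sum(p * (i - mu_g) ** 2))
    mu_s = float(np.sum(p * s))
    f[f"{sz}Variance"] = float(np.sum(p * (s - mu_s) ** 2))
    f[f"{sz}Entropy"] = _entropy(p.reshape(-1))
    prefix = "Run" if kind == "Run" else "Zone"
    f[f"LowGrayLevel{prefix}Emphasis"] = float(np.sum(P / i**2) / N)
    f[f"HighGrayLevel{prefix}Emphasis"] = float(np.sum(P * i**2) / N)
    sm = "ShortRun" if kind == "Run" else "SmallArea"
    lg = "LongRun" if kind == "Run" else "LargeArea"
    f[f"{sm}LowGrayLevelEmphasis"] = float(np.sum(P / (i**2 * s**2)) / N)
    f[f"{sm}HighGrayLevelEmphasis"] = float(np.sum(P * i**2 / s**2) / N)
    f[f"{lg}LowGrayLevelEmphasis"] = float(np.sum(P * s**2 / i**2) / N)
    f[f"{lg}HighGrayLevelEmphasis"] = float(np.sum(P * i**2 * s**2) / N)
    return f


def glrlm_features(stack: np.ndarray, n_voxels: int) -> tuple[dict[str, float], dict[str, str]]:
    per_dir = [
        _run_type_features(stack[d], n_voxels, "Run") for d in range(stack.shape[0])
    ]
    names = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in names}, {}


def glszm_features(P: np.ndarray, n_voxels: int) -> tuple[dict[str, float], dict[str, str]]:
    return _run_type_features(P, n_voxels, "Area"), {}


def gldm_features(P: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    ng, nd = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    N = P.sum()
    p = P / N
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    f: dict[str, float] = {}
    f["SmallDependenceEmphasis"] = float(np.sum(P / j**2) / N)
    f["LargeDependenceEmphasis"] = float(np.sum(P * j**2) / N)
    f["GrayLevelNonUniformity"] = float(np.sum(pg**2) / N)
    f["DependenceNonUniformity"] = float(np.sum(pd_**2) / N)
    f["DependenceNonUniformityNormalized"] = float(np.sum(pd_**2) / N**2)
    mu_g = float(np.sum(p * i))
    f["GrayLevelVariance"] = float(np.sum(p * (i - mu_g) ** 2))
    mu_d = float(np.sum(p * j))
    f["DependenceVariance"] = float(np.sum(p * (j - mu_d) ** 2))
    f["DependenceEntropy"] = _entropy(p.reshape(-1))
    f["LowGrayLevelEmphasis"] = float(np.sum(P / i**2) / N)
    f["HighGrayLevelEmphasis"] = float(np.sum(P * i**2) / N)
    f["SmallDependenceLowGrayLevelEmphasis"] = float(np.sum(P / (i**2 * j**2)) / N)
    f["SmallDependenceHighGrayLevelEmphasis"] = float(np.sum(P * i**2 / j**2) / N)
    f["LargeDependenceLowGrayLevelEmphasis"] = float(np.sum(P * j**2 / i**2) / N)
    f["LargeDependenceHighGrayLevelEmphasis"] = float(np.sum(P * i**2 * j**2) / N)
    return f, {}


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    ng = len(n_i)
    nvp = n_i.sum()
    p = n_i / nvp
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    f: dict[str, float] = {}
    denom_coarse = float(np.sum(p * s_i))
    f["Coarseness"] = 1.0 / denom_coarse if denom_coarse > 0 else 1e6
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi_ > 0) & (pj_ > 0)
        f["Contrast"] = float(
            np.sum(pi_[both] * pj_[both] * (ii[both] - jj[both]) ** 2)
            / (ngp * (ngp - 1))
            * np.sum(s_i)
            / nvp
        )
        denom_busy = float(np.sum(np.abs((i * p)[present][:, None] - (i * p)[present][None, :])))
        f["Busyness"] = denom_coarse / denom_busy if denom_busy > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i, s_i, indexing="ij")
        f["Complexity"] = float(
            np.sum(
                np.abs(ii[both] - jj[both])
                * (pi_[both] * si_[both] + pj_[both] * sj_[both])
                / (pi_[both] + pj_[both])
            )
            / nvp
        )
        sum_s = float(np.sum(s_i))
        f["Strength"] = (
            float(np.sum((pi_[both] + pj_[both]) * (ii[both] - jj[both]) ** 2)) / sum_s
            if sum_s > 0
            else 0.0
        )
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f, {}


def texture_features(matrices: dict) -> tuple[dict[str, float], dict[str, str]]:
    """All texture features from a `texture_matrices` result, with class
    prefixes ('glcm_Contrast', ...). Undefined features carry reasons."""
    n_vox = matrices["n_voxels"]
    feats: dict[str, float] = {}
    undef: dict[str, str] = {}
    for cls, (fd, ud) in {
        "glcm": glcm_features(matrices["glcm"]),
        "glrlm": glrlm_features(matrices["glrlm"], n_vox),
        "glszm": glszm_features(matrices["glszm"], n_vox),
        "gldm": gldm_features(matrices["gldm"]),
        "ngtdm": ngtdm_features(*matrices["ngtdm"]),
    }.items():
        for k, v in fd.items():
            feats[f"{cls}_{k}"] = v
        for k, v in ud.items():
            undef[f"{cls}_{k}"] = v
    return feats, undef
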