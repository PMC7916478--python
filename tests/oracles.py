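"""Independent brute-force oracles for the texture matrices and features.

Everything here is written as naive nested loops straight from the matrix
definitions (pair counting, line walking, flood fill, neighbourhood scans)
and deliberately shares no code with the vectorized implementations in
glioscan.radiomics.texture.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def all_directions(ndim):
    dirs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if any(off):
            nz = [o for o in off if o != 0]
            if nz[0] > 0:
                dirs.append(off)
    return dirs


def neighbors(ndim):
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]


def _in_grid(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def oracle_glcm(levels, mask, ng):
    """Symmetric normalized co-occurrence matrices, one per direction."""
    shape = levels.shape
    dirs = all_directions(levels.ndim)
    out = []
    for d in dirs:
        M = np.zeros((ng, ng))
        for pos in itertools.product(*(range(s) for s in shape)):
            if not mask[pos]:
                continue
            for sign in (+1, -1):
                nb = tuple(p + sign * o for p, o in zip(pos, d))
                if _in_grid(nb, shape) and mask[nb]:
                    M[levels[pos] - 1, levels[nb] - 1] += 1
        if M.sum() > 0:
            M = M / M.sum()
        out.append(M)
    return np.array(out)


def oracle_glrlm(levels, mask, ng):
    """Run-length count matrices by walking each line voxel by voxel."""
    shape = levels.shape
    dirs = all_directions(levels.ndim)
    maxlen = max(shape)
    out = []
    for d in dirs:
        M = np.zeros((ng, maxlen))
        for pos in itertools.product(*(range(s) for s in shape)):
            if not mask[pos]:
                continue
            prev = tuple(p - o for p, o in zip(pos, d))
            if _in_grid(prev, shape) and mask[prev] and levels[prev] == levels[pos]:
                continue  # not a run start
            length = 1
            cur = pos
            while True:
                nxt = tuple(p + o for p, o in zip(cur, d))
                if _in_grid(nxt, shape) and mask[nxt] and levels[nxt] == levels[pos]:
                    length += 1
                    cur = nxt
                else:
                    break
            M[levels[pos] - 1, length - 1] += 1
        out.append(M)
    return np.array(out)


def oracle_glszm(levels, mask, ng):
    """Zone-size counts via breadth-first flood fill (full connectivity)."""
    shape = levels.shape
    nbrs = neighbors(levels.ndim)
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for pos in itertools.product(*(range(s) for s in shape)):
        if not mask[pos] or seen[pos]:
            continue
        g = levels[pos]
        stack = [pos]
        seen[pos] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in nbrs:
                nb = tuple(p + o for p, o in zip(cur, d))
                if (_in_grid(nb, shape) and mask[nb] and not seen[nb]
                        and levels[nb] == g):
                    seen[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    maxsize = max(s for _, s in zones)
    M = np.zeros((ng, maxsize))
    for g, s in zones:
        M[g - 1, s - 1] += 1
    return M


def oracle_gldm(levels, mask, ng, alpha=0):
    """Dependence counts: neighbours within alpha of the centre, plus one."""
    shape = levels.shape
    nbrs = neighbors(levels.ndim)
    rows = []
    for pos in itertools.product(*(range(s) for s in shape)):
        if not mask[pos]:
            continue
        dep = 1
        for d in nbrs:
            nb = tuple(p + o for p, o in zip(pos, d))
            if _in_grid(nb, shape) and mask[nb] and abs(int(levels[nb]) - int(levels[pos])) <= alpha:
                dep += 1
        rows.append((levels[pos], dep))
    maxdep = max(d for _, d in rows)
    M = np.zeros((ng, maxdep))
    for g, d in rows:
        M[g - 1, d - 1] += 1
    return M


def oracle_ngtdm(levels, mask, ng):
    shape = levels.shape
    nbrs = neighbors(levels.ndim)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for pos in itertools.product(*(range(s) for s in shape)):
        if not mask[pos]:
            continue
        vals = []
        for d in nbrs:
            nb = tuple(p + o for p, o in zip(pos, d))
            if _in_grid(nb, shape) and mask[nb]:
                vals.append(levels[nb])
        if not vals:
            continue
        g = levels[pos]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(vals) / len(vals))
    return n_i, s_i


# ---------------------------------------------------------------- features

def _ent(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


def oracle_glcm_features(stack):
    """Per-direction features from the standard definitions, angle-averaged.
    Correlation is omitted when a direction has zero marginal variance."""
    per_dir = []
    for P in stack:
        ng = P.shape[0]
        f = {}
        px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
        ux = sum((i + 1) * px[i] for i in range(ng))
        sig2 = sum(px[i] * (i + 1 - ux) ** 2 for i in range(ng))
        f["Autocorrelation"] = sum(P[i][j] * (i + 1) * (j + 1)
                                   for i in range(ng) for j in range(ng))
        f["JointAverage"] = ux
        for name, k in [("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)]:
            f[name] = sum(P[i][j] * (i + j + 2 - 2 * ux) ** k
                          for i in range(ng) for j in range(ng))
        f["Contrast"] = sum(P[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
        if sig2 > 0:
            f["Correlation"] = (f["Autocorrelation"] - ux * ux) / sig2
        pd_ = [sum(P[i][j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
               for k in range(ng)]
        da = sum(k * pd_[k] for k in range(ng))
        f["DifferenceAverage"] = da
        f["DifferenceEntropy"] = _ent(pd_)
        f["DifferenceVariance"] = sum(pd_[k] * (k - da) ** 2 for k in range(ng))
        ps_ = [sum(P[i][j] for i in range(ng) for j in range(ng) if i + j + 2 == k)
               for k in range(2, 2 * ng + 1)]
        f["SumAverage"] = sum((k + 2) * ps_[k] for k in range(len(ps_)))
        f["SumEntropy"] = _ent(ps_)
        f["SumSquares"] = sum(P[i][j] * (i + 1 - ux) ** 2
                              for i in range(ng) for j in range(ng))
        f["JointEnergy"] = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
        f["JointEntropy"] = _ent([P[i][j] for i in range(ng) for j in range(ng)])
        f["Id"] = sum(P[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
        f["Idm"] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
        f["InverseVariance"] = sum(P[i][j] / (i - j) ** 2
                                   for i in range(ng) for j in range(ng) if i != j)
        f["MaximumProbability"] = max(P[i][j] for i in range(ng) for j in range(ng))
        per_dir.append(f)
    keys = set().union(*per_dir)
    out = {}
    for k in keys:
        if all(k in f for f in per_dir):
            out[k] = sum(f[k] for f in per_dir) / len(per_dir)
    return out


def _oracle_run_zone(P, n_vox, kind):
    ng, ns = P.shape
    N = P.sum()
    f = {}
    small = "ShortRunEmphasis" if kind == "Run" else "SmallAreaEmphasis"
    large = "LongRunEmphasis" if kind == "Run" else "LargeAreaEmphasis"
    f[small] = sum(P[i][s] / (s + 1) ** 2 for i in range(ng) for s in range(ns)) / N
    f[large] = sum(P[i][s] * (s + 1) ** 2 for i in range(ng) for s in range(ns)) / N
    pg = [sum(P[i][s] for s in range(ns)) for i in range(ng)]
    ps = [sum(P[i][s] for i in range(ng)) for s in range(ns)]
    f["GrayLevelNonUniformity"] = sum(g * g for g in pg) / N
    f["GrayLevelNonUniformityNormalized"] = sum(g * g for g in pg) / N**2
    key = "RunLengthNonUniformity" if kind == "Run" else "SizeZoneNonUniformity"
    f[key] = sum(s * s for s in ps) / N
    f[key + "Normalized"] = sum(s * s for s in ps) / N**2
    f["RunPercentage" if kind == "Run" else "ZonePercentage"] = N / n_vox
    mu_g = sum((i + 1) * pg[i] for i in range(ng)) / N
    f["GrayLevelVariance"] = sum(P[i][s] * (i + 1 - mu_g) ** 2
                                 for i in range(ng) for s in range(ns)) / N
    mu_s = sum((s + 1) * ps[s] for s in range(ns)) / N
    szvar = "RunVariance" if kind == "Run" else "ZoneVariance"
    f[szvar] = sum(P[i][s] * (s + 1 - mu_s) ** 2
                   for i in range(ng) for s in range(ns)) / N
    f["RunEntropy" if kind == "Run" else "ZoneEntropy"] = _ent(
        [P[i][s] / N for i in range(ng) for s in range(ns)]
    )
    pre = "Run" if kind == "Run" else "Zone"
    f[f"LowGrayLevel{pre}Emphasis"] = sum(P[i][s] / (i + 1) ** 2
                                          for i in range(ng) for s in range(ns)) / N
    f[f"HighGrayLevel{pre}Emphasis"] = sum(P[i][s] * (i + 1) ** 2
                                           for i in range(ng) for s in range(ns)) / N
    sm = "ShortRun" if kind == "Run" else "SmallArea"
    lg = "LongRun" if kind == "Run" else "LargeArea"
    f[f"{sm}LowGrayLevelEmphasis"] = sum(
        P[i][s] / ((i + 1) ** 2 * (s + 1) ** 2) for i in range(ng) for s in range(ns)) / N
    f[f"{sm}HighGrayLevelEmphasis"] = sum(
        P[i][s] * (i + 1) ** 2 / (s + 1) ** 2 for i in range(ng) for s in range(ns)) / N
    f[f"{lg}LowGrayLevelEmphasis"] = sum(
        P[i][s] * (s + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for s in range(ns)) / N
    f[f"{lg}HighGrayLevelEmphasis"] = sum(
        P[i][s] * (i + 1) ** 2 * (s + 1) ** 2 for i in range(ng) for s in range(ns)) / N
    return f


def oracle_glrlm_features(stack, n_vox):
    per_dir = [_oracle_run_zone(P, n_vox, "Run") for P in stack]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


def oracle_glszm_features(P, n_vox):
    return _oracle_run_zone(P, n_vox, "Zone")


def oracle_gldm_features(P):
    ng, nd = P.shape
    N = P.sum()
    f = {}
    f["SmallDependenceEmphasis"] = sum(P[i][j] / (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)) / N
    f["LargeDependenceEmphasis"] = sum(P[i][j] * (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)) / N
    pg = [sum(P[i][j] for j in range(nd)) for i in range(ng)]
    pdep = [sum(P[i][j] for i in range(ng)) for j in range(nd)]
    f["GrayLevelNonUniformity"] = sum(g * g for g in pg) / N
    f["DependenceNonUniformity"] = sum(d * d for d in pdep) / N
    f["DependenceNonUniformityNormalized"] = sum(d * d for d in pdep) / N**2
    mu_g = sum((i + 1) * pg[i] for i in range(ng)) / N
    f["GrayLevelVariance"] = sum(P[i][j] * (i + 1 - mu_g) ** 2
                                 for i in range(ng) for j in range(nd)) / N
    mu_d = sum((j + 1) * pdep[j] for j in range(nd)) / N
    f["DependenceVariance"] = sum(P[i][j] * (j + 1 - mu_d) ** 2
                                  for i in range(ng) for j in range(nd)) / N
    f["DependenceEntropy"] = _ent([P[i][j] / N for i in range(ng) for j in range(nd)])
    f["LowGrayLevelEmphasis"] = sum(P[i][j] / (i + 1) ** 2
                                    for i in range(ng) for j in range(nd)) / N
    f["HighGrayLevelEmphasis"] = sum(P[i][j] * (i + 1) ** 2
                                     for i in range(ng) for j in range(nd)) / N
    f["SmallDependenceLowGrayLevelEmphasis"] = sum(
        P[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nd)) / N
    f["SmallDependenceHighGrayLevelEmphasis"] = sum(
        P[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    f["LargeDependenceLowGrayLevelEmphasis"] = sum(
        P[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    f["LargeDependenceHighGrayLevelEmphasis"] = sum(
        P[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nd)) / N
    return f


def oracle_ngtdm_features(n_i, s_i):
    ng = len(n_i)
    nvp = sum(n_i)
    p = [n / nvp for n in n_i]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    f = {}
    denom = sum(p[i] * s_i[i] for i in range(ng))
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * sum(s_i) / nvp
        )
        busy = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        f["Busyness"] = denom / busy if busy > 0 else 0.0
        f["Complexity"] = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        sum_s = sum(s_i)
        f["Strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / sum_s
            if sum_s > 0 else 0.0
        )
    else:
        f.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0, "Strength": 0.0})
    return f


def oracle_all_features(levels, mask, ng):
    """Every texture feature, keyed like texture_features output."""
    n_vox = int(mask.sum())
    out = {}
    for k, v in oracle_glcm_features(oracle_glcm(levels, mask, ng)).items():
        out[f"glcm_{k}"] = v
    for k, v in oracle_glrlm_features(oracle_glrlm(levels, mask, ng), n_vox).items():
        out[f"glrlm_{k}"] = v
    for k, v in oracle_glszm_features(oracle_glszm(levels, mask, ng), n_vox).items():
        out[f"glszm_{k}"] = v
    for k, v in oracle_gldm_features(oracle_gldm(levels, mask, ng)).items():
        out[f"gldm_{k}"] = v
    for k, v in oracle_ngtdm_features(*oracle_ngtdm(levels, mask, ng)).items():
        out[f"ngtdm_{k}"] = v
    return out
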