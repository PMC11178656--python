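"""Independent brute-force reference implementations.

Everything here is written as plain per-voxel / per-pair loops straight
from the textbook definitions, deliberately sharing no code with the
package implementation: texture matrices are accumulated pair by pair,
zones grown by explicit flood fill, runs walked voxel by voxel, and the
AUC counted over all sample pairs.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)

DIRECTIONS_13 = []
for _dx in (-1, 0, 1):
    for _dy in (-1, 0, 1):
        for _dz in (-1, 0, 1):
            if (_dx, _dy, _dz) == (0, 0, 0):
                continue
            if _dx > 0 or (_dx == 0 and _dy > 0) or (_dx == 0 and _dy == 0 and _dz > 0):
                DIRECTIONS_13.append((_dx, _dy, _dz))

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= pi < si for pi, si in zip(p, shape))


def _level(levels, p):
    return int(levels[p]) if _inside(levels.shape, p) else 0


# ---------------------------------------------------------------------------
# first order


def naive_first_order(values, bin_width, voxel_volume=1.0, anchor="roi_min"):
    x = sorted(float(v) for v in np.ravel(values))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    energy = sum(v * v for v in x)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)

    lv = naive_discretize(x, bin_width, anchor)
    counts = {}
    for l in lv:
        counts[l] = counts.get(l, 0) + 1
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * math.log2(p + EPS) for p in probs)
    uniformity = sum(p * p for p in probs)

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": x[0],
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else float("nan"),
        "Kurtosis": m4 / m2**2 if m2 > 0 else float("nan"),
        "Variance": m2,
        "Uniformity": uniformity,
    }


def naive_discretize(values, bin_width, anchor="roi_min"):
    """Bin assignment by explicit edge search (mirrors np.digitize semantics)."""
    vals = [float(v) for v in np.ravel(values)]
    vmin, vmax = min(vals), max(vals)
    low = vmin if anchor == "roi_min" else math.floor(vmin / bin_width) * bin_width
    edges = list(np.arange(low, vmax + 2 * bin_width, bin_width))
    out = []
    for v in vals:
        k = 0
        while k < len(edges) and v >= edges[k]:
            k += 1
        out.append(max(k, 1))
    return out


# ---------------------------------------------------------------------------
# GLCM


def naive_glcm_matrices(levels):
    """One symmetric normalized co-occurrence matrix per direction."""
    levels = np.asarray(levels)
    lmax = int(levels.max())
    shape = levels.shape
    matrices = []
    for d in DIRECTIONS_13:
        M = np.zeros((lmax + 1, lmax + 1))
        for p in np.ndindex(shape):
            a = _level(levels, p)
            if a == 0:
                continue
            q = tuple(pi + di for pi, di in zip(p, d))
            b = _level(levels, q)
            if b == 0:
                continue
            M[a, b] += 1
            M[b, a] += 1
        if M.sum() > 0:
            matrices.append(M[1:, 1:] / M.sum())
    return matrices


def _glcm_features_from_matrix(P):
    L = P.shape[0]
    iv = list(range(1, L + 1))
    px = [sum(P[i - 1, j - 1] for j in iv) for i in iv]
    present = [i for i in iv if px[i - 1] > 0]
    ng = len(present)
    mu = sum(px[i - 1] * i for i in iv)
    sigma2 = sum(px[i - 1] * (i - mu) ** 2 for i in iv)
    pd = {}
    ps = {}
    for i in iv:
        for j in iv:
            pd[abs(i - j)] = pd.get(abs(i - j), 0.0) + P[i - 1, j - 1]
            ps[i + j] = ps.get(i + j, 0.0) + P[i - 1, j - 1]
    da = sum(k * v for k, v in pd.items())
    hxy = -sum(P[i - 1, j - 1] * math.log2(P[i - 1, j - 1] + EPS) for i in iv for j in iv)
    hx = -sum(px[i - 1] * math.log2(px[i - 1] + EPS) for i in iv)
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * px[j - 1] + EPS) for i in iv for j in iv
    )
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * math.log2(px[i - 1] * px[j - 1] + EPS)
        for i in iv
        for j in iv
    )
    autoc = sum(P[i - 1, j - 1] * i * j for i in iv for j in iv)
    if ng <= 1:
        mcc = 1.0
    else:
        Q = np.zeros((ng, ng))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * px[k - 1])
                    for k in present
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, ev[-2]))
    return {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": sum(
            P[i - 1, j - 1] * (i + j - 2 * mu) ** 4 for i in iv for j in iv
        ),
        "ClusterShade": sum(P[i - 1, j - 1] * (i + j - 2 * mu) ** 3 for i in iv for j in iv),
        "ClusterTendency": sum(
            P[i - 1, j - 1] * (i + j - 2 * mu) ** 2 for i in iv for j in iv
        ),
        "Contrast": sum(P[i - 1, j - 1] * (i - j) ** 2 for i in iv for j in iv),
        "Correlation": (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v + EPS) for v in pd.values()),
        "DifferenceVariance": sum(v * (k - da) ** 2 for k, v in pd.items()),
        "JointEnergy": sum(P[i - 1, j - 1] ** 2 for i in iv for j in iv),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Mcc": mcc,
        "Idm": sum(v / (1.0 + k**2) for k, v in pd.items()),
        "Idmn": sum(v / (1.0 + (k / ng) ** 2) for k, v in pd.items()),
        "Id": sum(v / (1.0 + k) for k, v in pd.items()),
        "Idn": sum(v / (1.0 + k / ng) for k, v in pd.items()),
        "InverseVariance": sum(v / k**2 for k, v in pd.items() if k > 0),
        "MaximumProbability": float(P.max()),
        "SumAverage": sum(k * v for k, v in ps.items()),
        "SumEntropy": -sum(v * math.log2(v + EPS) for v in ps.values()),
        "SumSquares": sigma2,
    }


def naive_glcm(levels):
    feats = [_glcm_features_from_matrix(P) for P in naive_glcm_matrices(levels)]
    return {k: sum(f[k] for f in feats) / len(feats) for k in feats[0]}


# ---------------------------------------------------------------------------
# GLRLM


def naive_runs(levels, d):
    """All (gray level, run length) pairs along direction d, walked voxelwise."""
    levels = np.asarray(levels)
    runs = []
    for p in np.ndindex(levels.shape):
        a = _level(levels, p)
        if a == 0:
            continue
        prev = tuple(pi - di for pi, di in zip(p, d))
        if _level(levels, prev) == a:
            continue  # not a run start
        length = 1
        q = tuple(pi + di for pi, di in zip(p, d))
        while _level(levels, q) == a:
            length += 1
            q = tuple(qi + di for qi, di in zip(q, d))
        runs.append((a, length))
    return runs


def _run_style_features(pairs, n_voxels, kind):
    nr = len(pairs)
    ci = {}
    cj = {}
    cell = {}
    for i, j in pairs:
        ci[i] = ci.get(i, 0) + 1
        cj[j] = cj.get(j, 0) + 1
        cell[(i, j)] = cell.get((i, j), 0) + 1
    mu_i = sum(i for i, _ in pairs) / nr
    mu_j = sum(j for _, j in pairs) / nr
    short, long_ = (f"Short{kind}", f"Long{kind}") if kind == "Run" else (
        f"Small{kind}", f"Large{kind}")
    return {
        f"{short}Emphasis": sum(1.0 / j**2 for _, j in pairs) / nr,
        f"{long_}Emphasis": sum(j**2 for _, j in pairs) / nr,
        "GrayLevelNonUniformity": sum(c**2 for c in ci.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in ci.values()) / nr**2,
        "SizeNonUniformity": sum(c**2 for c in cj.values()) / nr,
        "SizeNonUniformityNormalized": sum(c**2 for c in cj.values()) / nr**2,
        "CountFraction": nr / n_voxels,
        "GrayLevelVariance": sum((i - mu_i) ** 2 for i, _ in pairs) / nr,
        "SizeVariance": sum((j - mu_j) ** 2 for _, j in pairs) / nr,
        "Entropy": -sum(
            (c / nr) * math.log2(c / nr + EPS) for c in cell.values()
        ),
        "LowGrayLevelEmphasis": sum(1.0 / i**2 for i, _ in pairs) / nr,
        "HighGrayLevelEmphasis": sum(i**2 for i, _ in pairs) / nr,
        f"{short}LowGrayLevelEmphasis": sum(1.0 / (i**2 * j**2) for i, j in pairs) / nr,
        f"{short}HighGrayLevelEmphasis": sum(i**2 / j**2 for i, j in pairs) / nr,
        f"{long_}LowGrayLevelEmphasis": sum(j**2 / i**2 for i, j in pairs) / nr,
        f"{long_}HighGrayLevelEmphasis": sum(i**2 * j**2 for i, j in pairs) / nr,
    }


def naive_glrlm(levels):
    levels = np.asarray(levels)
    n_voxels = int((levels > 0).sum())
    per_dir = []
    for d in DIRECTIONS_13:
        v = _run_style_features(naive_runs(levels, d), n_voxels, "Run")
        per_dir.append(
            {
                "ShortRunEmphasis": v["ShortRunEmphasis"],
                "LongRunEmphasis": v["LongRunEmphasis"],
                "GrayLevelNonUniformity": v["GrayLevelNonUniformity"],
                "GrayLevelNonUniformityNormalized": v["GrayLevelNonUniformityNormalized"],
                "RunLengthNonUniformity": v["SizeNonUniformity"],
                "RunLengthNonUniformityNormalized": v["SizeNonUniformityNormalized"],
                "RunPercentage": v["CountFraction"],
                "GrayLevelVariance": v["GrayLevelVariance"],
                "RunVariance": v["SizeVariance"],
                "RunEntropy": v["Entropy"],
                "LowGrayLevelRunEmphasis": v["LowGrayLevelEmphasis"],
                "HighGrayLevelRunEmphasis": v["HighGrayLevelEmphasis"],
                "ShortRunLowGrayLevelEmphasis": v["ShortRunLowGrayLevelEmphasis"],
                "ShortRunHighGrayLevelEmphasis": v["ShortRunHighGrayLevelEmphasis"],
                "LongRunLowGrayLevelEmphasis": v["LongRunLowGrayLevelEmphasis"],
                "LongRunHighGrayLevelEmphasis": v["LongRunHighGrayLevelEmphasis"],
            }
        )
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def naive_zones(levels):
    """(gray level, size) of every 26-connected equal-level zone (flood fill)."""
    levels = np.asarray(levels)
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    for p in np.ndindex(levels.shape):
        a = _level(levels, p)
        if a == 0 or visited[p]:
            continue
        stack = [p]
        visited[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                r = tuple(qi + di for qi, di in zip(q, d))
                if _inside(levels.shape, r) and not visited[r] and _level(levels, r) == a:
                    visited[r] = True
                    stack.append(r)
        zones.append((a, size))
    return zones


def naive_glszm(levels):
    levels = np.asarray(levels)
    n_voxels = int((levels > 0).sum())
    v = _run_style_features(naive_zones(levels), n_voxels, "Area")
    return {
        "SmallAreaEmphasis": v["SmallAreaEmphasis"],
        "LargeAreaEmphasis": v["LargeAreaEmphasis"],
        "GrayLevelNonUniformity": v["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": v["GrayLevelNonUniformityNormalized"],
        "SizeZoneNonUniformity": v["SizeNonUniformity"],
        "SizeZoneNonUniformityNormalized": v["SizeNonUniformityNormalized"],
        "ZonePercentage": v["CountFraction"],
        "GrayLevelVariance": v["GrayLevelVariance"],
        "ZoneVariance": v["SizeVariance"],
        "ZoneEntropy": v["Entropy"],
        "LowGrayLevelZoneEmphasis": v["LowGrayLevelEmphasis"],
        "HighGrayLevelZoneEmphasis": v["HighGrayLevelEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": v["SmallAreaLowGrayLevelEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": v["SmallAreaHighGrayLevelEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": v["LargeAreaLowGrayLevelEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": v["LargeAreaHighGrayLevelEmphasis"],
    }


# ---------------------------------------------------------------------------
# NGTDM


def naive_ngtdm(levels):
    levels = np.asarray(levels)
    n_i = {}
    s_i = {}
    nvp = 0
    for p in np.ndindex(levels.shape):
        a = _level(levels, p)
        if a == 0:
            continue
        nbrs = []
        for d in NEIGHBORS_26:
            q = tuple(pi + di for pi, di in zip(p, d))
            b = _level(levels, q)
            if b > 0:
                nbrs.append(b)
        if not nbrs:
            continue
        nvp += 1
        n_i[a] = n_i.get(a, 0) + 1
        s_i[a] = s_i.get(a, 0.0) + abs(a - sum(nbrs) / len(nbrs))
    p_i = {a: c / nvp for a, c in n_i.items()}
    present = sorted(p_i)
    ngp = len(present)
    ps = sum(p_i[a] * s_i[a] for a in present)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p_i[a] * p_i[b] * (a - b) ** 2 for a in present for b in present)
            / (ngp * (ngp - 1))
            * sum(s_i.values())
            / nvp
        )
        denom = sum(abs(a * p_i[a] - b * p_i[b]) for a in present for b in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(
            abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
            for a in present
            for b in present
        ) / nvp
        ssum = sum(s_i.values())
        strength = (
            sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in present for b in present) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def naive_gldm(levels, alpha=0):
    levels = np.asarray(levels)
    n_voxels = int((levels > 0).sum())
    pairs = []
    for p in np.ndindex(levels.shape):
        a = _level(levels, p)
        if a == 0:
            continue
        dep = 1  # the center voxel counts
        for d in NEIGHBORS_26:
            b = _level(levels, tuple(pi + di for pi, di in zip(p, d)))
            if b > 0 and abs(b - a) <= alpha:
                dep += 1
        pairs.append((a, dep))
    v = _run_style_features(pairs, n_voxels, "Dependence")
    return {
        "SmallDependenceEmphasis": v["SmallDependenceEmphasis"],
        "LargeDependenceEmphasis": v["LargeDependenceEmphasis"],
        "GrayLevelNonUniformity": v["GrayLevelNonUniformity"],
        "DependenceNonUniformity": v["SizeNonUniformity"],
        "DependenceNonUniformityNormalized": v["SizeNonUniformityNormalized"],
        "GrayLevelVariance": v["GrayLevelVariance"],
        "DependenceVariance": v["SizeVariance"],
        "DependenceEntropy": v["Entropy"],
        "LowGrayLevelEmphasis": v["LowGrayLevelEmphasis"],
        "HighGrayLevelEmphasis": v["HighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": v["SmallDependenceLowGrayLevelEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": v["SmallDependenceHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": v["LargeDependenceLowGrayLevelEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": v["LargeDependenceHighGrayLevelEmphasis"],
    }


NAIVE_TEXTURE = {
    "GLCM": naive_glcm,
    "GLRLM": naive_glrlm,
    "GLSZM": naive_glszm,
    "NGTDM": naive_ngtdm,
    "GLDM": naive_gldm,
}


# ---------------------------------------------------------------------------
# kinetics and AUC


def naive_ttp(tac, midpoints_min, cutoff_min=3.0):
    """Per-TAC time of maximum after the cutoff; earliest frame on ties."""
    best_t, best_v = None, None
    for t, v in zip(midpoints_min, tac):
        if t <= cutoff_min:
            continue
        if best_v is None or v > best_v:
            best_t, best_v = t, v
    return best_t


def naive_slope_per_hour(tac, midpoints_min, n_last=3):
    t = np.asarray(midpoints_min[-n_last:]) / 60.0
    y = np.asarray(tac[-n_last:])
    return float(np.polyfit(t, y, 1)[0])


def naive_auc(values, y):
    """All-pairs Mann-Whitney count, ties credited one half."""
    pos = [v for v, yi in zip(values, y) if yi]
    neg = [v for v, yi in zip(values, y) if not yi]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
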