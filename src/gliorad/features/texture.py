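"""Gray-level texture matrices and their 75 standard features.

All families operate on a 3-D integer *level grid*: discretized gray
levels 1..Ng inside the ROI and 0 outside. Conventions follow the
IBSI-standardized reference definitions:

* GLCM  (24 features) — symmetric co-occurrence over the 13 unique 3-D
  unit-distance directions; features computed per direction, then averaged.
* GLRLM (16) — runs of consecutive equal levels per direction (13),
  features averaged over directions.
* GLSZM (16) — zones as 26-connected components of equal level; a single
  matrix.
* NGTDM (5)  — absolute difference from the mean level of the 26-
  neighborhood (in-mask neighbors only).
* GLDM  (14) — dependence counts with 26-neighborhood and level-difference
  tolerance alpha = 0; the dependence size includes the center voxel.

Out-of-mask neighbors never contribute. A single-voxel ROI yields NaN for
every feature (flagged missing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "TEXTURE_FAMILIES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "unique_direction_offsets",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "texture_features",
    "all_texture_features",
]

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Mcc", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

TEXTURE_FAMILIES = {
    "GLCM": GLCM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSZM": GLSZM_NAMES,
    "NGTDM": NGTDM_NAMES,
    "GLDM": GLDM_NAMES,
}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def unique_direction_offsets() -> list[tuple[int, int, int]]:
    """The 13 unit-distance 3-D directions unique up to sign."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if dx > 0 or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0):
                    offsets.append((dx, dy, dz))
    return offsets


def _all_neighbor_offsets() -> list[tuple[int, int, int]]:
    offs = unique_direction_offsets()
    return offs + [tuple(-c for c in o) for o in offs]


def _shifted(a: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """b[p] = a[p + d], with ``fill`` outside the grid."""
    out = np.full_like(a, fill)
    src = tuple(slice(max(di, 0), a.shape[k] + min(di, 0)) for k, di in enumerate(d))
    dst = tuple(slice(max(-di, 0), a.shape[k] + min(-di, 0)) for k, di in enumerate(d))
    out[dst] = a[src]
    return out


def _crop(levels: np.ndarray) -> np.ndarray:
    nz = np.nonzero(levels)
    if len(nz[0]) == 0:
        raise ValueError("empty level grid (no in-mask voxels)")
    sl = tuple(slice(int(c.min()), int(c.max()) + 1) for c in nz)
    return np.ascontiguousarray(levels[sl])


def _nan_result(names) -> dict[str, float]:
    return {n: float("nan") for n in names}


# ---------------------------------------------------------------------------
# GLCM

def _glcm_matrix(levels: np.ndarray, offset: tuple[int, int, int],
                 lmax: int) -> np.ndarray:
    nbr = _shifted(levels, offset)
    valid = (levels > 0) & (nbr > 0)
    a = levels[valid]
    b = nbr[valid]
    counts = np.bincount(a * (lmax + 1) + b, minlength=(lmax + 1) ** 2)
    C = counts.reshape(lmax + 1, lmax + 1)[1:, 1:].astype(float)
    return C + C.T  # symmetric co-occurrence


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    lmax = P.shape[0]
    i = np.arange(1, lmax + 1, dtype=float)
    px = P.sum(axis=1)  # == py by symmetry
    present = px > 0
    ng = int(present.sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")

    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    # diagonal / cross-diagonal marginals
    k_diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(k_diff.ravel(), weights=P.ravel(), minlength=lmax)
    kd = np.arange(p_diff.size, dtype=float)
    k_sum = (ii + jj).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=P.ravel(), minlength=2 * lmax + 1)
    ks = np.arange(p_sum.size, dtype=float)

    da = float((kd * p_diff).sum())
    hxy = float(-(P * np.log2(P + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(P * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    autocorr = float((P * ii * jj).sum())
    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient over present levels
    if ng <= 1:
        mcc = 1.0
    else:
        Pp = P[np.ix_(present, present)]
        pxp = px[present]
        A = Pp / pxp[:, None]
        B = Pp / pxp[None, :]
        Q = A @ B.T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size >= 2 else 1.0

    inv_var = float((p_diff[1:] / kd[1:] ** 2).sum()) if p_diff.size > 1 else 0.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float((P * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((P * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((P * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float((p_diff * (kd - da) ** 2).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Mcc": float(mcc),
        "Idm": float((p_diff / (1.0 + kd**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (kd / ng) ** 2)).sum()),
        "Id": float((p_diff / (1.0 + kd)).sum()),
        "Idn": float((p_diff / (1.0 + kd / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(levels: np.ndarray) -> dict[str, float]:
    """Co-occurrence features averaged over the 13 directions."""
    levels = _crop(np.asarray(levels))
    if np.count_nonzero(levels) < 2:
        return _nan_result(GLCM_NAMES)
    lmax = int(levels.max())
    per_angle = []
    for off in unique_direction_offsets():
        C = _glcm_matrix(levels, off, lmax)
        s = C.sum()
        if s == 0:
            continue
        per_angle.append(_glcm_single(C / s))
    if not per_angle:
        return _nan_result(GLCM_NAMES)
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def _run_length_matrix(levels: np.ndarray, d: tuple[int, int, int],
                       lmax: int) -> np.ndarray:
    inmask = levels > 0
    prev = _shifted(levels, tuple(-c for c in d))
    nxt = _shifted(levels, d)
    start = inmask & (prev != levels)
    cont = inmask & (nxt == levels)  # run continues one step further

    lengths = np.where(start, 1, 0)
    chain = cont.copy()  # cont holding for k consecutive steps from p
    alive = start & chain
    k = 1
    while alive.any():
        lengths[alive] += 1
        chain = chain & _shifted(cont, tuple(k * c for c in d), fill=False)
        alive = start & chain
        k += 1
    run_levels = levels[start]
    run_lengths = lengths[start]
    max_len = int(run_lengths.max())
    counts = np.bincount(
        (run_levels - 1) * max_len + (run_lengths - 1),
        minlength=lmax * max_len,
    )
    return counts.reshape(lmax, max_len).astype(float)


def _glrlm_single(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    iv = np.arange(1, P.shape[0] + 1, dtype=float)
    jv = np.arange(1, P.shape[1] + 1, dtype=float)
    pi = P.sum(axis=1)  # per gray level
    pj = P.sum(axis=0)  # per run length
    p = P / nr
    mu_i = float((pi / nr * iv).sum())
    mu_j = float((pj / nr * jv).sum())
    return {
        "ShortRunEmphasis": float((pj / jv**2).sum() / nr),
        "LongRunEmphasis": float((pj * jv**2).sum() / nr),
        "GrayLevelNonUniformity": float((pi**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pi**2).sum() / nr**2),
        "RunLengthNonUniformity": float((pj**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pj**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((pi / nr * (iv - mu_i) ** 2).sum()),
        "RunVariance": float((pj / nr * (jv - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((pi / iv**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((pi * iv**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / np.outer(iv**2, jv**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * np.outer(iv**2, 1 / jv**2)).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * np.outer(1 / iv**2, jv**2)).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * np.outer(iv**2, jv**2)).sum() / nr),
    }


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    levels = _crop(np.asarray(levels))
    n_voxels = int(np.count_nonzero(levels))
    if n_voxels < 2:
        return _nan_result(GLRLM_NAMES)
    lmax = int(levels.max())
    per_angle = [
        _glrlm_single(_run_length_matrix(levels, d, lmax), n_voxels)
        for d in unique_direction_offsets()
    ]
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

def _zone_list(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(zone gray level, zone size) for every 26-connected equal-level zone."""
    zone_levels, zone_sizes = [], []
    for lev in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == lev, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zone_levels.extend([int(lev)] * n)
            zone_sizes.extend(sizes.tolist())
    return np.asarray(zone_levels, dtype=float), np.asarray(zone_sizes, dtype=float)


def _zone_style_features(z_i: np.ndarray, z_j: np.ndarray, n_voxels: int,
                         names: tuple[str, ...], size_word: str) -> dict[str, float]:
    """Shared machinery for GLSZM and GLDM (both are level x size tabulations
    where each zone/voxel contributes one count)."""
    nz = float(z_i.size)
    ci = np.bincount(z_i.astype(int))[1:].astype(float)  # per gray level
    cj = np.bincount(z_j.astype(int))[1:].astype(float)  # per size
    mu_i = z_i.mean()
    mu_j = z_j.mean()
    # probabilities over distinct (i, j) cells for the entropy
    combo = z_i.astype(np.int64) * (int(z_j.max()) + 1) + z_j.astype(np.int64)
    cell_counts = np.unique(combo, return_counts=True)[1].astype(float)
    p_cell = cell_counts / nz
    small, large, low, high = (
        f"Small{size_word}", f"Large{size_word}", "LowGrayLevel", "HighGrayLevel")
    vals = {
        f"{small}Emphasis": float((1.0 / z_j**2).mean()),
        f"{large}Emphasis": float((z_j**2).mean()),
        "GrayLevelNonUniformity": float((ci**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((ci**2).sum() / nz**2),
        "GrayLevelVariance": float(((z_i - mu_i) ** 2).mean()),
        f"{low}Emphasis": float((1.0 / z_i**2).mean()),
        f"{high}Emphasis": float((z_i**2).mean()),
        f"{small}{low}Emphasis": float((1.0 / (z_i**2 * z_j**2)).mean()),
        f"{small}{high}Emphasis": float((z_i**2 / z_j**2).mean()),
        f"{large}{low}Emphasis": float((z_j**2 / z_i**2).mean()),
        f"{large}{high}Emphasis": float((z_i**2 * z_j**2).mean()),
        "_size_nonuniformity": float((cj**2).sum() / nz),
        "_size_nonuniformity_normalized": float((cj**2).sum() / nz**2),
        "_size_variance": float(((z_j - mu_j) ** 2).mean()),
        "_entropy": float(-(p_cell * np.log2(p_cell + _EPS)).sum()),
        "_count_fraction": float(nz / n_voxels),
    }
    return vals


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    """Size-zone features from the single 26-connectivity zone matrix."""
    levels = _crop(np.asarray(levels))
    n_voxels = int(np.count_nonzero(levels))
    if n_voxels < 2:
        return _nan_result(GLSZM_NAMES)
    z_i, z_j = _zone_list(levels)
    v = _zone_style_features(z_i, z_j, n_voxels, GLSZM_NAMES, "Area")
    return {
        "SmallAreaEmphasis": v["SmallAreaEmphasis"],
        "LargeAreaEmphasis": v["LargeAreaEmphasis"],
        "GrayLevelNonUniformity": v["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": v["GrayLevelNonUniformityNormalized"],
        "SizeZoneNonUniformity": v["_size_nonuniformity"],
        "SizeZoneNonUniformityNormalized": v["_size_nonuniformity_normalized"],
        "ZonePercentage": v["_count_fraction"],
        "GrayLevelVariance": v["GrayLevelVariance"],
        "ZoneVariance": v["_size_variance"],
        "ZoneEntropy": v["_entropy"],
        "LowGrayLevelZoneEmphasis": v["LowGrayLevelEmphasis"],
        "HighGrayLevelZoneEmphasis": v["HighGrayLevelEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": v["SmallAreaLowGrayLevelEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": v["SmallAreaHighGrayLevelEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": v["LargeAreaLowGrayLevelEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": v["LargeAreaHighGrayLevelEmphasis"],
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """Neighborhood gray-tone difference features (26-neighborhood, distance 1)."""
    levels = _crop(np.asarray(levels))
    inmask = levels > 0
    if int(inmask.sum()) < 2:
        return _nan_result(NGTDM_NAMES)
    kernel = _STRUCT_26.astype(float).copy()
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(levels.astype(float) * inmask, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(inmask.astype(float), kernel, mode="constant", cval=0.0)
    has_nbr = inmask & (nbr_cnt > 0)

    lev = levels[has_nbr].astype(float)
    abar = nbr_sum[has_nbr] / nbr_cnt[has_nbr]
    nvp = float(lev.size)
    lmax = int(lev.max())
    n_i = np.bincount(lev.astype(int), minlength=lmax + 1)[1:].astype(float)
    s_i = np.bincount(lev.astype(int), weights=np.abs(lev - abar), minlength=lmax + 1)[1:]
    p_i = n_i / nvp
    iv = np.arange(1, lmax + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pi_p, iv_p, si_p = p_i[present], iv[present], s_i[present]
        diff2 = (iv_p[:, None] - iv_p[None, :]) ** 2
        contrast = float(
            (pi_p[:, None] * pi_p[None, :] * diff2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        absdiff = np.abs(iv_p[:, None] * pi_p[:, None] - iv_p[None, :] * pi_p[None, :])
        denom_busy = float(absdiff.sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        pspj = pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :]
        complexity = float(
            (np.abs(iv_p[:, None] - iv_p[None, :]) * pspj / (pi_p[:, None] + pi_p[None, :])).sum()
            / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_p[:, None] + pi_p[None, :]) * diff2).sum()) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# GLDM

def gldm_features(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    """Dependence features: a neighbor is dependent when its level differs
    from the center by at most ``alpha``; dependence size = dependent
    neighbors + 1 (the center itself)."""
    levels = _crop(np.asarray(levels))
    inmask = levels > 0
    n_voxels = int(inmask.sum())
    if n_voxels < 2:
        return _nan_result(GLDM_NAMES)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _all_neighbor_offsets():
        nbr = _shifted(levels, off)
        dep += (np.abs(nbr - levels) <= alpha) & (nbr > 0)
    z_i = levels[inmask].astype(float)
    z_j = (dep[inmask] + 1).astype(float)
    v = _zone_style_features(z_i, z_j, n_voxels, GLDM_NAMES, "Dependence")
    return {
        "SmallDependenceEmphasis": v["SmallDependenceEmphasis"],
        "LargeDependenceEmphasis": v["LargeDependenceEmphasis"],
        "GrayLevelNonUniformity": v["GrayLevelNonUniformity"],
        "DependenceNonUniformity": v["_size_nonuniformity"],
        "DependenceNonUniformityNormalized": v["_size_nonuniformity_normalized"],
        "GrayLevelVariance": v["GrayLevelVariance"],
        "DependenceVariance": v["_size_variance"],
        "DependenceEntropy": v["_entropy"],
        "LowGrayLevelEmphasis": v["LowGrayLevelEmphasis"],
        "HighGrayLevelEmphasis": v["HighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": v["SmallDependenceLowGrayLevelEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": v["SmallDependenceHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": v["LargeDependenceLowGrayLevelEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": v["LargeDependenceHighGrayLevelEmphasis"],
    }


_DISPATCH = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "NGTDM": ngtdm_features,
    "GLDM": gldm_features,
}


def texture_features(levels: np.ndarray, family: str) -> dict[str, float]:
    """Compute one family's features on a level grid (0 = outside mask)."""
    if family not in _DISPATCH:
        raise ValueError(f"unknown texture family {family!r}; expected one of {sorted(_DISPATCH)}")
    if np.count_nonzero(levels) == 0:
        raise ValueError("empty mask")
    return _DISPATCH[family](levels)


def all_texture_features(levels: np.ndarray) -> dict[str, dict[str, float]]:
    """All 75 texture features, keyed by family then feature name."""
    return {fam: texture_features(levels, fam) for fam in TEXTURE_FAMILIES}
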