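"""Gray-level texture matrices and their canonical feature sets.

Five matrix families are computed from a discretized ROI (integer levels
``1..n_levels``, 0 = background):

* GLCM  — co-occurrence over the 13 unique 3D offsets at distance 1,
  symmetrized and normalized per offset; 22 features averaged over offsets.
* GLRLM — run lengths along the same 13 directions; 16 features averaged.
* GLSZM — 26-connected iso-level zones; 16 features.
* GLDM  — dependence counts in the 26-neighborhood with similarity
  tolerance α = 0; the dependence size of a voxel is 1 (itself) plus the
  number of in-ROI neighbors sharing its level; 14 features.
* NGTDM — mean absolute difference from the 26-neighborhood average;
  5 features. Voxels with no in-ROI neighbor are excluded.

Degenerate (single-level) ROIs use fixed conventions: Correlation = 1,
IMC1/IMC2 = 0, entropies = 0.

All builders are vectorized; exhaustive per-voxel enumeration oracles for
each family live in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

#: the 13 unique direction offsets of the 26-neighborhood (up to sign)
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_EPS = np.finfo(np.float64).eps

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
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

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def crop_to_roi(levels: np.ndarray) -> np.ndarray:
    """Crop a level array to the ROI bounding box (levels are 0 outside)."""
    idx = np.nonzero(levels)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return levels[sl]


def _offset_views(arr: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Views (x, y) such that y is x shifted by ``off`` inside the volume."""
    sl_x, sl_y = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_x.append(slice(0, n - o))
            sl_y.append(slice(o, n))
        else:
            sl_x.append(slice(-o, n))
            sl_y.append(slice(0, n + o))
    return arr[tuple(sl_x)], arr[tuple(sl_y)]


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetrized co-occurrence counts, shape (13, n_levels, n_levels)."""
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels), dtype=np.float64)
    for k, off in enumerate(DIRECTIONS_13):
        x, y = _offset_views(levels, off)
        m = (x > 0) & (y > 0)
        pairs = (x[m].astype(np.int64) - 1) * n_levels + (y[m] - 1)
        counts = np.bincount(pairs, minlength=n_levels * n_levels)
        P = counts.reshape(n_levels, n_levels).astype(np.float64)
        out[k] = P + P.T
    return out


def _glcm_features_one(P: np.ndarray) -> dict:
    Ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return {name: 0.0 for name in GLCM_NAMES}
    p = P / total
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())
    sigma2 = float(((ii - mu) ** 2 * p).sum())

    # p_{x+y} on k = 2..2Ng, p_{x-y} on k = 0..Ng-1
    ksum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * Ng - 1)
    kdiff = np.arange(0, Ng, dtype=np.float64)
    p_diff = np.zeros(Ng)
    sum_idx = (ii + jj - 2).astype(int)
    diff_idx = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sum_idx.ravel(), p.ravel())
    np.add.at(p_diff, diff_idx.ravel(), p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    joint_entropy = ent(p.ravel())
    hx = ent(px)
    hxy1 = float(-(p * np.log2(np.outer(px, px) + _EPS)).sum())
    pxpy = np.outer(px, px)
    hxy2 = float(-(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())

    if sigma2 > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0  # constant-ROI convention
    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))
    else:
        imc1 = 0.0
        imc2 = 0.0

    da = float((kdiff * p_diff).sum())
    offdiag = diff_idx > 0
    inv_var = float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum()) if offdiag.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((kdiff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) ** 2) / Ng ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": sigma2,
    }


def glcm_features(disc: DiscretizedROI) -> dict:
    """22 GLCM features, computed per offset and averaged over the 13."""
    levels = crop_to_roi(disc.gray_levels)
    mats = glcm_matrices(levels, disc.n_levels)
    per_dir = [_glcm_features_one(P) for P in mats if P.sum() > 0]
    if not per_dir:  # single isolated voxel: no pairs in any direction
        per_dir = [_glcm_features_one(np.ones((1, 1)))] if disc.n_levels == 1 else []
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def runs_along(levels: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """(run levels, run lengths) along one direction, via a shear transform.

    The volume is sheared so the requested direction becomes the first array
    axis, then all columns are run-length encoded in a single pass.
    """
    d = np.asarray(direction, dtype=int)
    prim = int(np.nonzero(d)[0][0])
    order = [prim] + [ax for ax in range(3) if ax != prim]
    lv = np.transpose(levels, order)
    dd = d[order]
    if dd[0] < 0:
        dd = -dd
    a, b = int(dd[1]), int(dd[2])
    n0, n1, n2 = lv.shape
    m1 = n1 + (n0 - 1) * (a != 0)
    m2 = n2 + (n0 - 1) * (b != 0)
    sheared = np.zeros((n0, m1, m2), dtype=lv.dtype)
    I, J, K = np.ogrid[:n0, :n1, :n2]
    off1 = (n0 - 1) if a > 0 else 0
    off2 = (n0 - 1) if b > 0 else 0
    sheared[I, J - a * I + off1, K - b * I + off2] = lv

    cols = sheared.reshape(n0, m1 * m2).T
    flat = np.concatenate(
        [cols, np.full((cols.shape[0], 1), -1, dtype=cols.dtype)], axis=1
    ).ravel()
    change = np.empty(flat.size, dtype=bool)
    change[0] = True
    np.not_equal(flat[1:], flat[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    vals = flat[starts]
    lens = np.diff(np.append(starts, flat.size))
    keep = vals > 0
    return vals[keep].astype(np.int64), lens[keep].astype(np.int64)


def glrlm_matrix(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts for one direction, shape (n_levels, max_run)."""
    vals, lens = runs_along(levels, direction)
    max_run = int(lens.max()) if lens.size else 1
    R = np.zeros((n_levels, max_run), dtype=np.float64)
    np.add.at(R, (vals - 1, lens - 1), 1.0)
    return R


def _gl_rl_features_one(R: np.ndarray, n_voxels: int) -> dict:
    Ng, Nr_max = R.shape
    Nr = R.sum()
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Nr_max + 1, dtype=np.float64)[None, :]
    p = R / Nr
    rg = R.sum(axis=1)  # per gray level
    rl = R.sum(axis=0)  # per run length
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pe = p[p > 0]
    return {
        "ShortRunEmphasis": float((R / j ** 2).sum() / Nr),
        "LongRunEmphasis": float((R * j ** 2).sum() / Nr),
        "GrayLevelNonUniformity": float((rg ** 2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((rg ** 2).sum() / Nr ** 2),
        "RunLengthNonUniformity": float((rl ** 2).sum() / Nr),
        "RunLengthNonUniformityNormalized": float((rl ** 2).sum() / Nr ** 2),
        "RunPercentage": float(Nr / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "RunVariance": float(((j - mu_j) ** 2 * p).sum()),
        "RunEntropy": float(-(pe * np.log2(pe)).sum()),
        "LowGrayLevelRunEmphasis": float((R / i ** 2).sum() / Nr),
        "HighGrayLevelRunEmphasis": float((R * i ** 2).sum() / Nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (i ** 2 * j ** 2)).sum() / Nr),
        "ShortRunHighGrayLevelEmphasis": float((R * i ** 2 / j ** 2).sum() / Nr),
        "LongRunLowGrayLevelEmphasis": float((R * j ** 2 / i ** 2).sum() / Nr),
        "LongRunHighGrayLevelEmphasis": float((R * i ** 2 * j ** 2).sum() / Nr),
    }


def glrlm_features(disc: DiscretizedROI) -> dict:
    """16 GLRLM features, per direction then averaged over the 13."""
    levels = crop_to_roi(disc.gray_levels)
    n_voxels = int((levels > 0).sum())
    per_dir = []
    for direction in DIRECTIONS_13:
        R = glrlm_matrix(levels, disc.n_levels, direction)
        per_dir.append(_gl_rl_features_one(R, n_voxels))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_zones(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """(zone levels, zone sizes) of 26-connected iso-level zones."""
    zl, zs = [], []
    for g in range(1, n_levels + 1):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT26)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zl.append(np.full(nlab, g, dtype=np.int64))
            zs.append(sizes.astype(np.int64))
    if not zl:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(zl), np.concatenate(zs)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts, shape (n_levels, max_zone_size)."""
    zl, zs = glszm_zones(levels, n_levels)
    max_size = int(zs.max()) if zs.size else 1
    Z = np.zeros((n_levels, max_size), dtype=np.float64)
    np.add.at(Z, (zl - 1, zs - 1), 1.0)
    return Z


def glszm_features(disc: DiscretizedROI) -> dict:
    levels = crop_to_roi(disc.gray_levels)
    n_voxels = int((levels > 0).sum())
    zl, zs = glszm_zones(levels, disc.n_levels)
    Nz = float(zl.size)
    i = zl.astype(np.float64)
    s = zs.astype(np.float64)
    p_i = np.bincount(zl, minlength=disc.n_levels + 1)[1:].astype(np.float64)
    p_s = np.bincount(zs)[1:].astype(np.float64)
    mu_i = float(i.sum() / Nz)
    mu_s = float(s.sum() / Nz)
    probs = np.bincount((zl - 1) * int(s.max()) + (zs - 1)).astype(np.float64)
    probs = probs[probs > 0] / Nz
    return {
        "SmallAreaEmphasis": float((1.0 / s ** 2).sum() / Nz),
        "LargeAreaEmphasis": float((s ** 2).sum() / Nz),
        "GrayLevelNonUniformity": float((p_i ** 2).sum() / Nz),
        "GrayLevelNonUniformityNormalized": float((p_i ** 2).sum() / Nz ** 2),
        "SizeZoneNonUniformity": float((p_s ** 2).sum() / Nz),
        "SizeZoneNonUniformityNormalized": float((p_s ** 2).sum() / Nz ** 2),
        "ZonePercentage": float(Nz / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2).sum() / Nz),
        "ZoneVariance": float(((s - mu_s) ** 2).sum() / Nz),
        "ZoneEntropy": float(-(probs * np.log2(probs)).sum()),
        "LowGrayLevelZoneEmphasis": float((1.0 / i ** 2).sum() / Nz),
        "HighGrayLevelZoneEmphasis": float((i ** 2).sum() / Nz),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (i ** 2 * s ** 2)).sum() / Nz),
        "SmallAreaHighGrayLevelEmphasis": float((i ** 2 / s ** 2).sum() / Nz),
        "LargeAreaLowGrayLevelEmphasis": float((s ** 2 / i ** 2).sum() / Nz),
        "LargeAreaHighGrayLevelEmphasis": float((i ** 2 * s ** 2).sum() / Nz),
    }


# ---------------------------------------------------------------------------
# GLDM

_OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def gldm_dependence(levels: np.ndarray) -> np.ndarray:
    """Per-voxel dependence size: 1 + equal-level in-ROI 26-neighbors."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        x, y = _offset_views(levels, off)
        sl_x = tuple(
            slice(0, n - o) if o >= 0 else slice(-o, n)
            for o, n in zip(off, levels.shape)
        )
        dep[sl_x] += ((x == y) & (y > 0) & (x > 0)).astype(np.int64)
    dep[levels > 0] += 1
    dep[levels == 0] = 0
    return dep


def gldm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts, shape (n_levels, max_dependence)."""
    dep = gldm_dependence(levels)
    roi = levels > 0
    g = levels[roi].astype(np.int64)
    d = dep[roi]
    D = np.zeros((n_levels, int(d.max())), dtype=np.float64)
    np.add.at(D, (g - 1, d - 1), 1.0)
    return D


def gldm_features(disc: DiscretizedROI) -> dict:
    levels = crop_to_roi(disc.gray_levels)
    D = gldm_matrix(levels, disc.n_levels)
    Ng, Nd = D.shape
    Nz = D.sum()
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Nd + 1, dtype=np.float64)[None, :]
    p = D / Nz
    dg = D.sum(axis=1)
    dd = D.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pe = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((D / j ** 2).sum() / Nz),
        "LargeDependenceEmphasis": float((D * j ** 2).sum() / Nz),
        "GrayLevelNonUniformity": float((dg ** 2).sum() / Nz),
        "DependenceNonUniformity": float((dd ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((dd ** 2).sum() / Nz ** 2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((j - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(pe * np.log2(pe)).sum()),
        "LowGrayLevelEmphasis": float((D / i ** 2).sum() / Nz),
        "HighGrayLevelEmphasis": float((D * i ** 2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (i ** 2 * j ** 2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * i ** 2 / j ** 2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * j ** 2 / i ** 2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * i ** 2 * j ** 2).sum() / Nz),
    }


# ---------------------------------------------------------------------------
# NGTDM

_KERNEL26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL26[1, 1, 1] = 0.0


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_g counts, s_g coarseness sums, N counted voxels)."""
    roi = (levels > 0).astype(np.float64)
    nbr_sum = ndimage.correlate(levels.astype(np.float64) * roi, _KERNEL26,
                                mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(roi, _KERNEL26, mode="constant", cval=0.0)
    valid = (levels > 0) & (nbr_cnt > 0)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n_g = np.zeros(n_levels)
    s_g = np.zeros(n_levels)
    g = levels[valid].astype(np.int64)
    np.add.at(n_g, g - 1, 1.0)
    np.add.at(s_g, g - 1, diff[valid])
    return n_g, s_g, int(valid.sum())


def ngtdm_features(disc: DiscretizedROI) -> dict:
    levels = crop_to_roi(disc.gray_levels)
    n_g, s_g, N = ngtdm_table(levels, disc.n_levels)
    p = n_g / N
    i = np.arange(1, disc.n_levels + 1, dtype=np.float64)
    present = p > 0
    Ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s_g[present]

    denom_coarse = float((pp * sp).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if Ngp > 1:
        pij = pp[:, None] * pp[None, :]
        d2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pij * d2).sum()) / (Ngp * (Ngp - 1)) * (s_g.sum() / N)
    else:
        contrast = 0.0

    busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
    busyness = denom_coarse / busy_den if busy_den > 0 else 0.0

    if Ngp > 1:
        num = np.abs(ip[:, None] - ip[None, :]) * (
            pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        ) / (pp[:, None] + pp[None, :])
        complexity = float(num.sum()) / N
        strength_num = float(((pp[:, None] + pp[None, :])
                              * (ip[:, None] - ip[None, :]) ** 2).sum())
        s_sum = float(s_g.sum())
        strength = strength_num / s_sum if s_sum > 0 else 0.0
    else:
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }
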