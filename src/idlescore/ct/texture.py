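"""First- and second-order texture features of a 3D volume of interest.

Second-order statistics follow the common radiomics formulations: gray-level
co-occurrence matrices (GLCM, 22 features) accumulated symmetrically at unit
displacement along 13 unique 3D lattice directions, and gray-level run-length
matrices (GLRLM, 11 features) computed for every direction x stride
combination with strides 2..5.  Per-matrix features are averaged over all
matrices to give a single rotation-pooled value per feature.

Gray levels are discretised with a fixed bin width (default 100, on the
HU-like scale of the normalised volume), anchored at the VOI minimum so that
levels start at 1.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

#: The 13 unique 3D lattice directions (half of the 26-neighbourhood).
DIRECTIONS_3D = (
    (1, 0, 0), (0, 1, 0), (1, 1, 0), (-1, 1, 0), (1, 0, 1), (1, 1, 1),
    (1, -1, 1), (0, 0, 1), (0, 1, 1), (0, -1, 1), (-1, 0, 1), (-1, 1, 1),
    (-1, -1, 1),
)

#: GLRLM stride (voxel distance) parameters.
GLRLM_DISTANCES = (2, 3, 4, 5)

GLCM_FEATURE_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_entropy",
    "dissimilarity", "energy", "entropy", "homogeneity1", "homogeneity2",
    "imc1", "imc2", "idmn", "idn", "inverse_variance", "max_probability",
    "sum_average", "sum_entropy", "sum_variance", "variance",
)

GLRLM_FEATURE_NAMES = (
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)

FIRST_ORDER_NAMES = (
    "mean", "median", "sd", "skewness", "kurtosis", "min", "max",
    "q10", "q25", "q75", "q90", "energy", "rms", "entropy", "uniformity",
)


def quantize(values: np.ndarray, bin_size: float = 100.0) -> np.ndarray:
    """Discretise intensities into 1-based gray levels of fixed bin width.

    Bins are anchored at the minimum of ``values`` so the lowest occupied
    level is always 1 (gray-level magnitudes enter several run-length
    features, so levels must be positive).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot quantize an empty set of voxels")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    levels = np.floor((values - values.min()) / bin_size).astype(np.int64) + 1
    return levels


def first_order_features(voxels: np.ndarray, bin_size: float = 100.0) -> "OrderedDict[str, float]":
    """Fifteen first-order intensity statistics of a voxel sample.

    Moments and quantiles are computed on the raw values; entropy (bits) and
    uniformity come from the fixed-bin-width histogram; ``energy`` is the sum
    of squared intensities and ``rms`` the root mean square.
    """
    v = np.asarray(voxels, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first-order features require at least one voxel")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite voxel intensities")
    from scipy import stats

    sd = float(v.std(ddof=0))
    out = OrderedDict()
    out["mean"] = float(v.mean())
    out["median"] = float(np.median(v))
    out["sd"] = sd
    out["skewness"] = float(stats.skew(v)) if sd > 0 else 0.0
    out["kurtosis"] = float(stats.kurtosis(v, fisher=False)) if sd > 0 else 0.0
    out["min"] = float(v.min())
    out["max"] = float(v.max())
    for q in (10, 25, 75, 90):
        out[f"q{q}"] = float(np.percentile(v, q))
    out["energy"] = float(np.sum(v ** 2))
    out["rms"] = float(np.sqrt(np.mean(v ** 2)))
    levels = quantize(v, bin_size)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / v.size
    out["entropy"] = float(-np.sum(p * np.log2(p)))
    out["uniformity"] = float(np.sum(p ** 2))
    return out


# ---------------------------------------------------------------------------
# GLCM

def _dense_levels(volume: np.ndarray, mask: np.ndarray, bin_size: float):
    """Quantised levels on the mask bounding box; 0 marks out-of-mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    m = mask[sub]
    vals = np.asarray(volume, dtype=float)[sub]
    dense = np.zeros(m.shape, dtype=np.int64)
    dense[m] = quantize(vals[m], bin_size)
    return dense, m


def glcm_matrix(dense: np.ndarray, offset) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix for one displacement.

    ``dense`` holds 1-based levels with 0 outside the VOI.  Each ordered
    voxel pair is accumulated in both orders and the matrix normalised to
    sum 1.  Returns an (L, L) matrix for levels 1..L; raises if the VOI has
    no valid pair along the offset.
    """
    n_levels = int(dense.max())
    a, b = _shifted_views(dense, offset)
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ValueError("no co-occurring voxel pairs along this direction")
    ai = a[valid] - 1
    bi = b[valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (ai, bi), 1.0)
    np.add.at(mat, (bi, ai), 1.0)
    return mat / mat.sum()


def _shifted_views(dense: np.ndarray, offset):
    sl_a, sl_b = [], []
    for d, o in zip(dense.shape, offset):
        if o >= 0:
            sl_a.append(slice(0, d - o))
            sl_b.append(slice(o, d))
        else:
            sl_a.append(slice(-o, d))
            sl_b.append(slice(0, d + o))
    return dense[tuple(sl_a)], dense[tuple(sl_b)]


def glcm_features_from_matrix(p: np.ndarray) -> "OrderedDict[str, float]":
    """The 22 co-occurrence features of one normalised symmetric GLCM."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma = float(np.sqrt(np.sum((i - mu) ** 2 * px)))

    # marginal distributions of i+j and |i-j|
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(ksum.size)
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(kdiff.size)
    s_idx = (ii + jj - 2).astype(int)
    d_idx = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, s_idx.ravel(), p.ravel())
    np.add.at(p_diff, d_idx.ravel(), p.ravel())

    def _ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    hxy = _ent(p.ravel())
    hx = _ent(px)
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    hxy2 = _ent(pxpy.ravel())

    out = OrderedDict()
    out["autocorrelation"] = float(np.sum(ii * jj * p))
    cc = ii + jj - 2 * mu
    out["cluster_prominence"] = float(np.sum(cc ** 4 * p))
    out["cluster_shade"] = float(np.sum(cc ** 3 * p))
    out["cluster_tendency"] = float(np.sum(cc ** 2 * p))
    out["contrast"] = float(np.sum((ii - jj) ** 2 * p))
    out["correlation"] = (
        float((np.sum(ii * jj * p) - mu * mu) / (sigma * sigma)) if sigma > 0 else 0.0
    )
    out["difference_entropy"] = _ent(p_diff)
    out["dissimilarity"] = float(np.sum(np.abs(ii - jj) * p))
    out["energy"] = float(np.sum(p ** 2))
    out["entropy"] = hxy
    out["homogeneity1"] = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    out["homogeneity2"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    out["imc1"] = float((hxy - hxy1) / hx) if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["imc2"] = float(np.sqrt(max(arg, 0.0)))
    out["idmn"] = float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng ** 2)))
    out["idn"] = float(np.sum(p / (1.0 + np.abs(ii - jj) / ng)))
    off = ii != jj
    out["inverse_variance"] = float(np.sum(p[off] / (ii - jj)[off] ** 2))
    out["max_probability"] = float(p.max())
    sa = float(np.sum(ksum * p_sum))
    out["sum_average"] = sa
    out["sum_entropy"] = _ent(p_sum)
    out["sum_variance"] = float(np.sum((ksum - sa) ** 2 * p_sum))
    out["variance"] = float(np.sum((ii - mu) ** 2 * p))
    return out


def glcm_features(volume, mask, bin_size: float = 100.0,
                  directions=DIRECTIONS_3D, return_matrices: bool = False):
    """Direction-averaged GLCM features of a VOI.

    One symmetric normalised matrix is built per direction at unit
    displacement; the 22 features are averaged over the directions that
    contain at least one voxel pair.  Raises if no direction does.
    """
    dense, _ = _dense_levels(volume, mask, bin_size)
    mats, feats = [], []
    for d in directions:
        try:
            m = glcm_matrix(dense, d)
        except ValueError:
            continue
        mats.append(m)
        feats.append(glcm_features_from_matrix(m))
    if not feats:
        raise ValueError("mask has no voxel pairs along any direction")
    out = OrderedDict(
        (k, float(np.mean([f[k] for f in feats]))) for k in GLCM_FEATURE_NAMES
    )
    if return_matrices:
        return out, mats
    return out


# ---------------------------------------------------------------------------
# GLRLM

def _glrlm_runs(coords: np.ndarray, levels: np.ndarray, direction, distance: int):
    """Vectorised run detection: (run levels, run lengths, counts)."""
    s = np.asarray(direction, dtype=np.int64) * int(distance)
    axis = int(np.nonzero(s)[0][0])
    t = np.floor_divide(coords[:, axis], s[axis])
    key = coords - t[:, None] * s
    # pack the 3D chain key into one integer so a single 2-key lexsort suffices
    kmin = key.min(axis=0)
    kr = key - kmin
    span = kr.max(axis=0).astype(np.int64) + 1
    enc = (kr[:, 0] * span[1] + kr[:, 1]) * span[2] + kr[:, 2]
    tr = t - t.min()
    order = np.argsort(enc * (tr.max() + 1) + tr, kind="stable")
    ke = enc[order]
    tt = t[order]
    lv = levels[order]
    same_chain = (ke[1:] == ke[:-1]) & (tt[1:] == tt[:-1] + 1)
    cont = same_chain & (lv[1:] == lv[:-1])
    breaks = np.flatnonzero(~cont)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [lv.size - 1]))
    run_lv = lv[starts]
    run_len = ends - starts + 1
    enc = run_lv * (run_len.max() + 1) + run_len
    uniq, counts = np.unique(enc, return_counts=True)
    base = run_len.max() + 1
    return uniq // base, uniq % base, counts


def glrlm_matrix(coords: np.ndarray, levels: np.ndarray, direction, distance: int):
    """Run-length matrix for one direction and stride.

    A run is a maximal chain of in-mask voxels at positions p, p+s, p+2s, ...
    (s = distance * direction) sharing one gray level; gaps in the mask and
    level changes both terminate runs.  Returns a dict {(level, length): count}.
    """
    gl, rl, c = _glrlm_runs(coords, levels, direction, distance)
    return {(int(g), int(l)): int(n) for g, l, n in zip(gl, rl, c)}


def glrlm_features_from_runs(runs, n_voxels: int) -> "OrderedDict[str, float]":
    """The 11 run-length features of one run-length matrix.

    ``runs`` is either a {(level, length): count} dict or an
    (levels, lengths, counts) array triple.
    """
    if isinstance(runs, dict):
        lev = np.array([k[0] for k in runs], dtype=float)
        rl = np.array([k[1] for k in runs], dtype=float)
        c = np.array(list(runs.values()), dtype=float)
    else:
        lev, rl, c = (np.asarray(a, dtype=float) for a in runs)
    nr = c.sum()
    out = OrderedDict()
    out["sre"] = float(np.sum(c / rl ** 2) / nr)
    out["lre"] = float(np.sum(c * rl ** 2) / nr)
    gl_tot = np.zeros(int(lev.max()) + 1)
    np.add.at(gl_tot, lev.astype(int), c)
    rl_tot = np.zeros(int(rl.max()) + 1)
    np.add.at(rl_tot, rl.astype(int), c)
    out["gln"] = float(np.sum(gl_tot ** 2) / nr)
    out["rln"] = float(np.sum(rl_tot ** 2) / nr)
    out["rp"] = float(nr / n_voxels)
    out["lglre"] = float(np.sum(c / lev ** 2) / nr)
    out["hglre"] = float(np.sum(c * lev ** 2) / nr)
    out["srlgle"] = float(np.sum(c / (lev ** 2 * rl ** 2)) / nr)
    out["srhgle"] = float(np.sum(c * lev ** 2 / rl ** 2) / nr)
    out["lrlgle"] = float(np.sum(c * rl ** 2 / lev ** 2) / nr)
    out["lrhgle"] = float(np.sum(c * lev ** 2 * rl ** 2) / nr)
    return out


def glrlm_features(volume, mask, bin_size: float = 100.0,
                   distances=GLRLM_DISTANCES, directions=DIRECTIONS_3D,
                   return_matrices: bool = False):
    """Run-length features averaged over every direction x stride matrix."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    coords = np.argwhere(mask).astype(np.int64)
    levels = quantize(np.asarray(volume, dtype=float)[mask], bin_size)
    n_vox = coords.shape[0]
    mats, feats = [], []
    for dist in distances:
        for d in directions:
            if return_matrices:
                runs = glrlm_matrix(coords, levels, d, dist)
            else:
                runs = _glrlm_runs(coords, levels, d, dist)
            if (len(runs) if isinstance(runs, dict) else runs[2].size) == 0:
                continue
            mats.append(runs)
            feats.append(glrlm_features_from_runs(runs, n_vox))
    if not feats:
        raise ValueError("no runs found")
    out = OrderedDict(
        (k, float(np.mean([f[k] for f in feats]))) for k in GLRLM_FEATURE_NAMES
    )
    if return_matrices:
        return out, mats
    return out
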