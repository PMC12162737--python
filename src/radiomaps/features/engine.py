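"""Batched, mask-aware computation of the 93-feature catalog.

Every kernel here operates on a *stack* of masked 2D regions at once: an
``(N, H, W)`` intensity array plus an ``(N, H, W)`` boolean mask.  Conventional
ROI extraction is simply a stack of size one; the parametric-map engine feeds
thousands of fixed-size tiles through the same kernels in a single call.
Because both paths share this code, a whole-image single-tile map reproduces
conventional extraction bit for bit.

Degenerate cases never raise: each feature comes back as a value array plus a
validity array, and undefined entries (e.g. GLCM correlation of a one-level
region, gray-tone features of a single-pixel mask) are flagged invalid.

Conventions (matching the public reference feature definitions):

* discretization: ``level = floor((I - min_masked)/bin_width) + 1``, then
  levels re-indexed to consecutive occupied integers; ``Ng`` = occupied count;
* logarithms are base 2 and ``0·log 0 = 0``;
* per-angle matrix features are averaged over angles that produced a
  non-empty matrix;
* first-order variance/skewness/kurtosis are population moments, kurtosis is
  non-excess (a normal distribution scores 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .catalog import ALL_FEATURES
from .settings import ExtractionSettings

__all__ = ["BatchResult", "DiscretizedStack", "discretize_stack", "extract_stack"]

#: Cap for NGTDM coarseness when its denominator vanishes (constant region).
COARSENESS_CAP = 1e6


@dataclass
class BatchResult:
    """Feature values and validity flags for a stack of N regions."""

    values: dict[str, np.ndarray]  # name -> (N,) float
    valid: dict[str, np.ndarray]  # name -> (N,) bool
    n_items: int

    def feature_names(self) -> tuple[str, ...]:
        return ALL_FEATURES


@dataclass
class DiscretizedStack:
    """Gray-level discretized stack: prerequisite of all matrix features."""

    levels: np.ndarray  # (N, H, W) int32, 0 outside the mask, 1..Ng inside
    mask: np.ndarray  # (N, H, W) bool
    ng: np.ndarray  # (N,) occupied level count
    counts: np.ndarray  # (N,) masked pixel count

    @property
    def max_level(self) -> int:
        return int(self.ng.max())


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_stack(
    stack: np.ndarray, mask: np.ndarray, bin_width: float
) -> DiscretizedStack:
    """Fixed-bin-width discretization anchored at each region's masked minimum."""
    X = np.asarray(stack, dtype=np.float64)
    M = np.asarray(mask, dtype=bool)
    if X.ndim != 3 or X.shape != M.shape:
        raise ValueError("stack and mask must share an (N, H, W) shape")
    if not np.all(np.isfinite(X[M])):
        raise ValueError("masked intensities must be finite")
    N = X.shape[0]
    counts = M.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise ValueError("every region in the stack must have a non-empty mask")

    mins = np.where(M, X, np.inf).min(axis=(1, 2))
    raw = np.floor((X - mins[:, None, None]) / float(bin_width)).astype(np.int64) + 1
    raw[~M] = 0

    # Re-index each region's occupied raw levels to consecutive 1..Ng.
    lmax = int(raw.max())
    occ = np.zeros((N, lmax + 1), dtype=bool)
    item_idx = np.nonzero(M)[0]
    occ[item_idx, raw[M]] = True
    occ[:, 0] = False
    rank = np.cumsum(occ, axis=1, dtype=np.int64)
    grid_item = np.arange(N)[:, None, None]
    levels = np.where(M, rank[grid_item, raw], 0).astype(np.int32)
    ng = rank[:, -1]
    return DiscretizedStack(levels=levels, mask=M, ng=ng, counts=counts)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _plog2p(p: np.ndarray) -> np.ndarray:
    """Elementwise -p*log2(p) with the 0·log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=np.float64)
    return np.divide(num, np.where(den != 0, den, 1.0))


def _offset_views(arr: np.ndarray, dr: int, dc: int):
    """Return paired views a, b of an (N, H, W) array offset by (dr, dc)."""
    _, H, W = arr.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        empty = arr[:, 0:0, 0:0]
        return empty, empty
    a = arr[:, r0:r1, c0:c1]
    b = arr[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a, b


def _angle_average(per_angle_vals, per_angle_valid):
    """Average per-angle feature values over the angles where defined."""
    vals = np.stack(per_angle_vals)  # (A, N)
    ok = np.stack(per_angle_valid)  # (A, N)
    w = ok.sum(axis=0)
    s = np.where(ok, np.nan_to_num(vals, nan=0.0), 0.0).sum(axis=0)
    out = np.where(w > 0, s / np.where(w > 0, w, 1), np.nan)
    return out, w > 0


def _group_starts(counts: np.ndarray) -> np.ndarray:
    ends = np.cumsum(counts)
    return ends - counts


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def _firstorder_batch(
    X: np.ndarray,
    disc: DiscretizedStack,
    pixel_area_mm2: float,
    slice_thickness_mm: float,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    M = disc.mask
    N = X.shape[0]
    counts = disc.counts
    vals_flat = X[M]
    starts = _group_starts(counts)

    names = (
        "Energy Entropy Minimum Maximum Mean Median Range Variance Skewness "
        "Kurtosis Uniformity RootMeanSquared TotalEnergy InterquartileRange "
        "MeanAbsoluteDeviation RobustMeanAbsoluteDeviation"
    ).split()
    res = {n: np.full(N, np.nan) for n in names}
    res["10Percentile"] = np.full(N, np.nan)
    res["90Percentile"] = np.full(N, np.nan)
    moment_ok = np.zeros(N, dtype=bool)
    rmad_ok = np.zeros(N, dtype=bool)

    # Items are processed in groups of equal pixel count so each group
    # vectorizes as an (n, c) matrix.
    for c in np.unique(counts):
        idx = np.nonzero(counts == c)[0]
        V = vals_flat[starts[idx][:, None] + np.arange(c)[None, :]]
        q = np.percentile(V, [10.0, 25.0, 50.0, 75.0, 90.0], axis=1)
        mean = V.mean(axis=1)
        energy = (V * V).sum(axis=1)
        dev = V - mean[:, None]
        m2 = (dev * dev).mean(axis=1)
        m3 = (dev**3).mean(axis=1)
        m4 = (dev**4).mean(axis=1)
        # Values inside the 10th-90th percentile window; for tiny regions the
        # window can be empty, leaving robust MAD undefined.
        inc = (V >= q[0][:, None]) & (V <= q[4][:, None])
        ninc = inc.sum(axis=1)
        ninc_safe = np.where(ninc > 0, ninc, 1)
        mean_in = (V * inc).sum(axis=1) / ninc_safe
        rmad = (np.abs(V - mean_in[:, None]) * inc).sum(axis=1) / ninc_safe
        rmad_ok[idx] = ninc > 0

        res["10Percentile"][idx] = q[0]
        res["90Percentile"][idx] = q[4]
        res["Median"][idx] = q[2]
        res["InterquartileRange"][idx] = q[3] - q[1]
        res["Minimum"][idx] = V.min(axis=1)
        res["Maximum"][idx] = V.max(axis=1)
        res["Range"][idx] = res["Maximum"][idx] - res["Minimum"][idx]
        res["Mean"][idx] = mean
        res["Energy"][idx] = energy
        res["TotalEnergy"][idx] = energy * pixel_area_mm2 * slice_thickness_mm
        res["RootMeanSquared"][idx] = np.sqrt(energy / c)
        res["MeanAbsoluteDeviation"][idx] = np.abs(dev).mean(axis=1)
        res["RobustMeanAbsoluteDeviation"][idx] = rmad
        res["Variance"][idx] = m2
        ok = m2 > 0
        moment_ok[idx] = ok
        with np.errstate(divide="ignore", invalid="ignore"):
            res["Skewness"][idx] = np.where(ok, m3 / np.where(ok, m2, 1) ** 1.5, np.nan)
            res["Kurtosis"][idx] = np.where(ok, m4 / np.where(ok, m2, 1) ** 2.0, np.nan)

    # Histogram features on the discretized levels.
    K = disc.max_level
    item_idx = np.nonzero(M)[0]
    hist = np.bincount(
        item_idx * (K + 1) + disc.levels[M], minlength=N * (K + 1)
    ).reshape(N, K + 1)[:, 1:]
    p = hist / counts[:, None]
    res["Entropy"] = _plog2p(p).sum(axis=1)
    res["Uniformity"] = (p * p).sum(axis=1)

    always = np.ones(N, dtype=bool)
    out = {}
    for name, arr in res.items():
        if name in ("Skewness", "Kurtosis"):
            ok = moment_ok
        elif name == "RobustMeanAbsoluteDeviation":
            ok = rmad_ok
        else:
            ok = always
        out[f"firstorder_{name}"] = (arr, ok.copy())
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_single_angle(P: np.ndarray, ng: np.ndarray):
    """24 GLCM features from a stack of (already symmetrized) count matrices."""
    N, K, _ = P.shape
    total = P.sum(axis=(1, 2))
    has = total > 0
    p = P / np.where(total > 0, total, 1.0)[:, None, None]
    iv = np.arange(1, K + 1, dtype=np.float64)
    px = p.sum(axis=2)  # (N, K) marginal over j
    py = p.sum(axis=1)
    ux = (px * iv).sum(axis=1)
    uy = (py * iv).sum(axis=1)
    sigx2 = (px * (iv[None, :] - ux[:, None]) ** 2).sum(axis=1)
    sigy2 = (py * (iv[None, :] - uy[:, None]) ** 2).sum(axis=1)

    II, JJ = np.meshgrid(iv, iv, indexing="ij")
    D = np.abs(II - JJ)

    # Cross-diagonal (i+j) and diagonal (|i-j|) marginal distributions.
    pflip = p[:, :, ::-1]
    pxy_sum = np.zeros((N, 2 * K - 1))
    for o in range(-(K - 1), K):
        pxy_sum[:, K - 1 - o] = pflip.diagonal(o, 1, 2).sum(axis=-1)
    ksum = np.arange(2 * K - 1, dtype=np.float64) + 2.0
    pxy_diff = np.zeros((N, K))
    pxy_diff[:, 0] = p.diagonal(0, 1, 2).sum(axis=-1)
    for d in range(1, K):
        pxy_diff[:, d] = p.diagonal(d, 1, 2).sum(axis=-1) + p.diagonal(-d, 1, 2).sum(
            axis=-1
        )
    kdiff = np.arange(K, dtype=np.float64)

    f = {}
    f["Autocorrelation"] = (p * (II * JJ)[None]).sum(axis=(1, 2))
    f["JointAverage"] = ux
    tplus = (II + JJ)[None] - (ux + uy)[:, None, None]
    f["ClusterProminence"] = (p * tplus**4).sum(axis=(1, 2))
    f["ClusterShade"] = (p * tplus**3).sum(axis=(1, 2))
    f["ClusterTendency"] = (p * tplus**2).sum(axis=(1, 2))
    f["Contrast"] = (p * (D * D)[None]).sum(axis=(1, 2))

    cov = f["Autocorrelation"] - ux * uy
    denom = np.sqrt(sigx2 * sigy2)
    corr_ok = has & (denom > 0)
    f["Correlation"] = np.where(corr_ok, _safe_div(cov, denom), np.nan)

    da = (pxy_diff * kdiff).sum(axis=1)
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _plog2p(pxy_diff).sum(axis=1)
    f["DifferenceVariance"] = (pxy_diff * (kdiff[None, :] - da[:, None]) ** 2).sum(
        axis=1
    )
    f["JointEnergy"] = (p * p).sum(axis=(1, 2))
    hxy = _plog2p(p).sum(axis=(1, 2))
    f["JointEntropy"] = hxy

    hx = _plog2p(px).sum(axis=1)
    hy = _plog2p(py).sum(axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    lg = np.zeros_like(pxpy)
    nz = pxpy > 0
    lg[nz] = np.log2(pxpy[nz])
    hxy1 = -(p * lg).sum(axis=(1, 2))
    hxy2 = -(pxpy * lg).sum(axis=(1, 2))
    hmax = np.maximum(hx, hy)
    f["Imc1"] = np.where(hmax > 0, _safe_div(hxy - hxy1, hmax), 0.0)
    f["Imc2"] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    f["Idm"] = (p / (1.0 + D * D)[None]).sum(axis=(1, 2))
    f["Id"] = (p / (1.0 + D)[None]).sum(axis=(1, 2))
    ng_safe = np.where(ng > 0, ng, 1).astype(np.float64)
    f["Idmn"] = (p / (1.0 + (D[None] / ng_safe[:, None, None]) ** 2)).sum(axis=(1, 2))
    f["Idn"] = (p / (1.0 + D[None] / ng_safe[:, None, None])).sum(axis=(1, 2))
    iv_off = np.where(D > 0, D, 1.0)
    f["InverseVariance"] = (np.where(D[None] > 0, p, 0.0) / (iv_off * iv_off)[None]).sum(
        axis=(1, 2)
    )
    f["MaximumProbability"] = p.max(axis=(1, 2))
    f["SumAverage"] = (pxy_sum * ksum).sum(axis=1)
    f["SumEntropy"] = _plog2p(pxy_sum).sum(axis=1)
    f["SumSquares"] = (p * (II[None] - ux[:, None, None]) ** 2).sum(axis=(1, 2))

    # MCC: square root of the second-largest eigenvalue of Q.  Absent levels
    # give zero rows/columns, contributing spurious zero eigenvalues only.
    nlev = (px > 0).sum(axis=1)
    inv_px = np.where(px > 0, 1.0 / np.where(px > 0, px, 1.0), 0.0)
    inv_py = np.where(py > 0, 1.0 / np.where(py > 0, py, 1.0), 0.0)
    B = p * inv_py[:, None, :]
    Q = inv_px[:, :, None] * np.einsum("nik,njk->nij", p, B)
    eig = np.sort(np.real(np.linalg.eigvals(Q)), axis=1)
    second = np.clip(eig[:, -2] if K >= 2 else np.zeros(N), 0.0, None)
    f["MCC"] = np.where(nlev > 1, np.sqrt(second), 1.0)

    valid = {name: has.copy() for name in f}
    valid["Correlation"] = corr_ok
    return f, valid


def _glcm_batch(disc: DiscretizedStack, settings: ExtractionSettings):
    levels = disc.levels
    N = levels.shape[0]
    K = max(disc.max_level, 1)
    d = settings.glcm_distance
    grid_item = np.arange(N)[:, None, None]

    per_vals: dict[str, list] = {}
    per_ok: dict[str, list] = {}
    for udr, udc in settings.angles_2d:
        a, b = _offset_views(levels, udr * d, udc * d)
        pair_ok = (a > 0) & (b > 0)
        it = np.broadcast_to(grid_item, a.shape)[pair_ok]
        ii = a[pair_ok].astype(np.int64) - 1
        jj = b[pair_ok].astype(np.int64) - 1
        idx = (it * K + ii) * K + jj
        P = np.bincount(idx, minlength=N * K * K).reshape(N, K, K).astype(np.float64)
        if settings.symmetric_glcm:
            P = P + P.transpose(0, 2, 1)
        f, ok = _glcm_single_angle(P, disc.ng)
        for name in f:
            per_vals.setdefault(name, []).append(f[name])
            per_ok.setdefault(name, []).append(ok[name])

    out = {}
    for name in per_vals:
        vals, ok = _angle_average(per_vals[name], per_ok[name])
        out[f"glcm_{name}"] = (vals, ok)
    return out


# ---------------------------------------------------------------------------
# shared machinery for (item, gray level, size) entry lists
# ---------------------------------------------------------------------------

def _entry_features(
    item: np.ndarray,
    lev: np.ndarray,
    size: np.ndarray,
    N: int,
    K: int,
    n_pixels: np.ndarray,
    prefix: str,
    names: dict[str, str],
):
    """Features shared by GLRLM/GLSZM/GLDM, all sums over (level i, size j) entries.

    ``names`` maps the generic keys (SmallEmphasis, LargeEmphasis, GLN, GLNN,
    SizeNonUniformity, SizeNonUniformityNormalized, Percentage, GLVariance,
    SizeVariance, Entropy, LowGL, HighGL, SmallLow, SmallHigh, LargeLow,
    LargeHigh) onto the class-specific feature names.
    """
    iv = lev.astype(np.float64)
    jv = size.astype(np.float64)
    ns = np.bincount(item, minlength=N).astype(np.float64)  # Nr / Nz per item

    def agg(w):
        return np.bincount(item, weights=w, minlength=N)

    inv_i2 = 1.0 / (iv * iv)
    inv_j2 = 1.0 / (jv * jv)
    f = {}
    f[names["SmallEmphasis"]] = agg(inv_j2) / ns
    f[names["LargeEmphasis"]] = agg(jv * jv) / ns
    f[names["LowGL"]] = agg(inv_i2) / ns
    f[names["HighGL"]] = agg(iv * iv) / ns
    f[names["SmallLow"]] = agg(inv_i2 * inv_j2) / ns
    f[names["SmallHigh"]] = agg(iv * iv * inv_j2) / ns
    f[names["LargeLow"]] = agg(jv * jv * inv_i2) / ns
    f[names["LargeHigh"]] = agg(iv * iv * jv * jv) / ns

    sg = np.bincount(item * (K + 1) + lev, minlength=N * (K + 1)).reshape(
        N, K + 1
    ).astype(np.float64)
    f[names["GLN"]] = (sg * sg).sum(axis=1) / ns
    f[names["GLNN"]] = (sg * sg).sum(axis=1) / (ns * ns)

    smax = int(size.max()) if size.size else 1
    sl = np.bincount(item * (smax + 1) + size, minlength=N * (smax + 1)).reshape(
        N, smax + 1
    ).astype(np.float64)
    f[names["SizeNonUniformity"]] = (sl * sl).sum(axis=1) / ns
    f[names["SizeNonUniformityNormalized"]] = (sl * sl).sum(axis=1) / (ns * ns)

    if names.get("Percentage"):
        f[names["Percentage"]] = ns / n_pixels

    mu_i = agg(iv) / ns
    f[names["GLVariance"]] = agg((iv - mu_i[item]) ** 2) / ns
    mu_j = agg(jv) / ns
    f[names["SizeVariance"]] = agg((jv - mu_j[item]) ** 2) / ns

    # Entropy over the normalized (level, size) cell distribution.
    cell = (item.astype(np.int64) * (K + 1) + lev) * (smax + 1) + size
    ccount = np.bincount(cell, minlength=N * (K + 1) * (smax + 1))
    nz = np.nonzero(ccount)[0]
    citem = nz // ((K + 1) * (smax + 1))
    pcell = ccount[nz] / ns[citem]
    f[names["Entropy"]] = np.bincount(
        citem, weights=_plog2p(pcell), minlength=N
    )

    valid = np.ones(N, dtype=bool)
    return {f"{prefix}_{k}": (v, valid.copy()) for k, v in f.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_from_lines(lines: np.ndarray, item_of_line: np.ndarray):
    """Maximal equal-level runs (level 0 breaks runs) from stacked 1D lines."""
    L = lines
    ncols = L.shape[1]
    prev = np.zeros_like(L)
    prev[:, 1:] = L[:, :-1]
    start = (L > 0) & (L != prev)
    flat = L.ravel()
    start_flat = start.ravel()
    rid = np.cumsum(start_flat)
    valid = flat > 0
    lengths = np.bincount(rid[valid])[1:]
    sp = np.nonzero(start_flat)[0]
    rlevel = flat[sp]
    ritem = item_of_line[sp // ncols]
    return ritem.astype(np.int64), rlevel.astype(np.int64), lengths.astype(np.int64)


def _lines_for_angle(levels: np.ndarray, dr: int, dc: int):
    """Rearrange an (N, H, W) level stack so scan lines along (dr, dc) become rows."""
    N, H, W = levels.shape
    if (dr, dc) in ((0, 1), (0, -1)):
        lines = levels.reshape(N * H, W)
        item = np.repeat(np.arange(N), H)
    elif (dr, dc) in ((1, 0), (-1, 0)):
        lines = levels.transpose(0, 2, 1).reshape(N * W, H)
        item = np.repeat(np.arange(N), W)
    else:
        # Diagonals: shear rows so each diagonal lands in one column.
        down_right = dr == dc
        Z = np.zeros((N, H, W + H - 1), dtype=levels.dtype)
        rows = np.arange(H)[:, None]
        cols = np.arange(W)[None, :]
        off = (H - 1 - rows) if down_right else rows
        Z[:, rows, cols + off] = levels
        lines = Z.transpose(0, 2, 1).reshape(N * (W + H - 1), H)
        item = np.repeat(np.arange(N), W + H - 1)
    return lines, item


_GLRLM_NAMES = {
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGL": "LowGrayLevelRunEmphasis",
    "HighGL": "HighGrayLevelRunEmphasis",
    "SmallLow": "ShortRunLowGrayLevelEmphasis",
    "SmallHigh": "ShortRunHighGrayLevelEmphasis",
    "LargeLow": "LongRunLowGrayLevelEmphasis",
    "LargeHigh": "LongRunHighGrayLevelEmphasis",
}


def _glrlm_batch(disc: DiscretizedStack, settings: ExtractionSettings):
    N = disc.levels.shape[0]
    K = max(disc.max_level, 1)
    per_vals: dict[str, list] = {}
    per_ok: dict[str, list] = {}
    for dr, dc in settings.angles_2d:
        lines, item_of_line = _lines_for_angle(disc.levels, dr, dc)
        ritem, rlevel, lengths = _runs_from_lines(lines, item_of_line)
        feats = _entry_features(
            ritem, rlevel, lengths, N, K, disc.counts, "glrlm", _GLRLM_NAMES
        )
        for name, (v, ok) in feats.items():
            per_vals.setdefault(name, []).append(v)
            per_ok.setdefault(name, []).append(ok)
    return {
        name: _angle_average(per_vals[name], per_ok[name]) for name in per_vals
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_GLSZM_NAMES = {
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGL": "LowGrayLevelZoneEmphasis",
    "HighGL": "HighGrayLevelZoneEmphasis",
    "SmallLow": "SmallAreaLowGrayLevelEmphasis",
    "SmallHigh": "SmallAreaHighGrayLevelEmphasis",
    "LargeLow": "LargeAreaLowGrayLevelEmphasis",
    "LargeHigh": "LargeAreaHighGrayLevelEmphasis",
}


def _glszm_batch(disc: DiscretizedStack, settings: ExtractionSettings):
    N, H, W = disc.levels.shape
    K = max(disc.max_level, 1)
    if settings.connectivity == 8:
        plane = np.ones((3, 3), dtype=int)
    else:
        plane = ndimage.generate_binary_structure(2, 1).astype(int)
    structure = np.zeros((3, 3, 3), dtype=int)
    structure[1] = plane  # zones never connect across stack items

    zitem, zlevel, zsize = [], [], []
    for g in range(1, K + 1):
        binm = disc.levels == g
        if not binm.any():
            continue
        lab, nlab = ndimage.label(binm, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        labs, first = np.unique(lab.ravel(), return_index=True)
        if labs[0] == 0:
            first = first[1:]
        items = first // (H * W)
        zitem.append(items)
        zlevel.append(np.full(nlab, g, dtype=np.int64))
        zsize.append(sizes.astype(np.int64))

    zitem = np.concatenate(zitem)
    zlevel = np.concatenate(zlevel)
    zsize = np.concatenate(zsize)
    return _entry_features(zitem, zlevel, zsize, N, K, disc.counts, "glszm", _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

_GLDM_NAMES = {
    "SmallEmphasis": "SmallDependenceEmphasis",
    "LargeEmphasis": "LargeDependenceEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "DependenceNonUniformity",
    "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
    "Percentage": None,
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "DependenceVariance",
    "Entropy": "DependenceEntropy",
    "LowGL": "LowGrayLevelEmphasis",
    "HighGL": "HighGrayLevelEmphasis",
    "SmallLow": "SmallDependenceLowGrayLevelEmphasis",
    "SmallHigh": "SmallDependenceHighGrayLevelEmphasis",
    "LargeLow": "LargeDependenceLowGrayLevelEmphasis",
    "LargeHigh": "LargeDependenceHighGrayLevelEmphasis",
}


def _gldm_batch(disc: DiscretizedStack, settings: ExtractionSettings):
    levels = disc.levels
    N = levels.shape[0]
    K = max(disc.max_level, 1)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for dr, dc in settings.neighbor_offsets:
        a, b = _offset_views(levels, dr, dc)
        if a.size == 0:
            continue
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= settings.gldm_alpha)
        sl_a, _ = _offset_slices_for(levels.shape, dr, dc)
        dep[(slice(None),) + sl_a] += ok
    M = disc.mask
    item = np.nonzero(M)[0].astype(np.int64)
    lev = levels[M].astype(np.int64)
    size = dep[M] + 1  # dependence 0 stored at size index 1
    feats = _entry_features(item, lev, size, N, K, disc.counts, "gldm", _GLDM_NAMES)
    # GLDM has no percentage feature; drop the unused key if present.
    feats.pop("gldm_None", None)
    return feats


def _offset_slices_for(shape, dr: int, dc: int):
    _, H, W = shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = (slice(r0, r1), slice(c0, c1))
    b = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    return a, b


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _ngtdm_batch(disc: DiscretizedStack, settings: ExtractionSettings):
    levels = disc.levels
    M = disc.mask
    N = levels.shape[0]
    K = max(disc.max_level, 1)
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for dr, dc in settings.neighbor_offsets:
        sl_a, sl_b = _offset_slices_for(levels.shape, dr, dc)
        a = levels[(slice(None),) + sl_a]
        b = levels[(slice(None),) + sl_b]
        if a.size == 0:
            continue
        ok = b > 0
        nsum[(slice(None),) + sl_a] += np.where(ok, b, 0)
        ncnt[(slice(None),) + sl_a] += ok

    valid_px = M & (ncnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(valid_px, nsum / np.where(ncnt > 0, ncnt, 1), 0.0)
    diff = np.where(valid_px, np.abs(levels - abar), 0.0)

    item = np.nonzero(valid_px)[0].astype(np.int64)
    lev = levels[valid_px].astype(np.int64)
    ni = np.bincount(item * (K + 1) + lev, minlength=N * (K + 1)).reshape(N, K + 1)[
        :, 1:
    ].astype(np.float64)
    si = np.bincount(
        item * (K + 1) + lev, weights=diff[valid_px], minlength=N * (K + 1)
    ).reshape(N, K + 1)[:, 1:]
    nvp = ni.sum(axis=1)
    has = nvp > 0
    nvp_safe = np.where(has, nvp, 1.0)
    pi = ni / nvp_safe[:, None]
    iv = np.arange(1, K + 1, dtype=np.float64)
    ngp = (ni > 0).sum(axis=1)

    psum = (pi * si).sum(axis=1)
    ssum = si.sum(axis=1)

    coarse = np.where(psum > 0, _safe_div(1.0, psum), COARSENESS_CAP)

    PiPj = pi[:, :, None] * pi[:, None, :]
    D2 = (iv[:, None] - iv[None, :]) ** 2
    pair_ok = (pi[:, :, None] > 0) & (pi[:, None, :] > 0)
    denom_ct = (ngp * (ngp - 1)).astype(np.float64)
    contrast = np.where(
        ngp > 1,
        _safe_div((PiPj * D2[None]).sum(axis=(1, 2)), denom_ct)
        * _safe_div(ssum, nvp_safe),
        0.0,
    )

    ipi = iv[None, :] * pi
    busy_den = np.where(pair_ok, np.abs(ipi[:, :, None] - ipi[:, None, :]), 0.0).sum(
        axis=(1, 2)
    )
    busyness = np.where(busy_den > 0, _safe_div(psum, busy_den), 0.0)

    pis = pi * si
    num_cx = np.where(
        pair_ok,
        np.abs(iv[None, :, None] - iv[None, None, :])
        * _safe_div(
            pis[:, :, None] + pis[:, None, :],
            np.where(pair_ok, pi[:, :, None] + pi[:, None, :], 1.0),
        ),
        0.0,
    ).sum(axis=(1, 2))
    complexity = _safe_div(num_cx, nvp_safe)

    num_st = np.where(
        pair_ok, (pi[:, :, None] + pi[:, None, :]) * D2[None], 0.0
    ).sum(axis=(1, 2))
    strength = np.where(ssum > 0, _safe_div(num_st, ssum), 0.0)

    out = {
        "ngtdm_Coarseness": coarse,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }
    return {k: (np.where(has, v, np.nan), has.copy()) for k, v in out.items()}


# ---------------------------------------------------------------------------
# top-level entry point
# ---------------------------------------------------------------------------

def extract_stack(
    stack: np.ndarray,
    mask: np.ndarray,
    pixel_area_mm2: float,
    slice_thickness_mm: float,
    settings: ExtractionSettings | None = None,
) -> BatchResult:
    """Compute all 93 features for every masked region in the stack."""
    if settings is None:
        settings = ExtractionSettings()
    X = np.asarray(stack, dtype=np.float64)
    M = np.asarray(mask, dtype=bool)
    disc = discretize_stack(X, M, settings.bin_width)

    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    feats.update(_firstorder_batch(X, disc, pixel_area_mm2, slice_thickness_mm))
    feats.update(_glcm_batch(disc, settings))
    feats.update(_gldm_batch(disc, settings))
    feats.update(_glrlm_batch(disc, settings))
    feats.update(_glszm_batch(disc, settings))
    feats.update(_ngtdm_batch(disc, settings))

    values = {}
    valid = {}
    for name in ALL_FEATURES:
        v, ok = feats[name]
        v = np.asarray(v, dtype=np.float64)
        ok = np.asarray(ok, dtype=bool) & np.isfinite(v)
        values[name] = np.where(ok, v, np.nan)
        valid[name] = ok
    return BatchResult(values=values, valid=valid, n_items=X.shape[0])
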