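"""Independent brute-force oracles for the texture-matrix features.

Everything here is written naively — dictionaries of matrix counts built by
explicit per-pixel loops, flood fill by hand, scalar formula evaluation — and
shares no code with the package's batched kernels.  Slow on purpose; used
only on tiny regions.
"""

from __future__ import annotations

import math

import numpy as np

EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
FOUR = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def bf_discretize(values: np.ndarray, mask: np.ndarray, bin_width: float):
    """Levels 1..Ng with consecutive re-indexing; 0 outside the mask."""
    h, w = values.shape
    masked = [values[r, c] for r in range(h) for c in range(w) if mask[r, c]]
    vmin = min(masked)
    raw = {}
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                raw[(r, c)] = int(math.floor((values[r, c] - vmin) / bin_width)) + 1
    occupied = sorted(set(raw.values()))
    remap = {g: i + 1 for i, g in enumerate(occupied)}
    levels = np.zeros((h, w), dtype=int)
    for (r, c), g in raw.items():
        levels[r, c] = remap[g]
    return levels, len(occupied)


def _xlog2(p):
    return -p * math.log2(p) if p > 0 else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def bf_glcm(levels, ng, angles=((0, 1), (1, 1), (1, 0), (1, -1)), distance=1,
            symmetric=True):
    """24 co-occurrence features, per-angle then averaged where defined."""
    h, w = levels.shape
    per_angle = []
    for (ur, uc) in angles:
        dr, dc = ur * distance, uc * distance
        counts = {}
        for r in range(h):
            for c in range(w):
                if levels[r, c] == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] != 0:
                    i, j = levels[r, c], levels[r2, c2]
                    counts[(i, j)] = counts.get((i, j), 0) + 1
                    if symmetric:
                        counts[(j, i)] = counts.get((j, i), 0) + 1
        total = sum(counts.values())
        if total == 0:
            per_angle.append(None)
            continue
        p = {k: v / total for k, v in counts.items()}
        per_angle.append(_glcm_formulas(p, ng))
    return _average_angles(per_angle)


def _glcm_formulas(p, ng):
    f = {}
    px, py = {}, {}
    for (i, j), v in p.items():
        px[i] = px.get(i, 0.0) + v
        py[j] = py.get(j, 0.0) + v
    ux = sum(i * v for i, v in px.items())
    uy = sum(j * v for j, v in py.items())
    sigx2 = sum(v * (i - ux) ** 2 for i, v in px.items())
    sigy2 = sum(v * (j - uy) ** 2 for j, v in py.items())

    psum, pdiff = {}, {}
    for (i, j), v in p.items():
        psum[i + j] = psum.get(i + j, 0.0) + v
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + v

    f["Autocorrelation"] = sum(v * i * j for (i, j), v in p.items())
    f["JointAverage"] = ux
    f["ClusterProminence"] = sum(v * (i + j - ux - uy) ** 4 for (i, j), v in p.items())
    f["ClusterShade"] = sum(v * (i + j - ux - uy) ** 3 for (i, j), v in p.items())
    f["ClusterTendency"] = sum(v * (i + j - ux - uy) ** 2 for (i, j), v in p.items())
    f["Contrast"] = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    cov = sum(v * (i - ux) * (j - uy) for (i, j), v in p.items())
    denom = math.sqrt(sigx2 * sigy2)
    f["Correlation"] = cov / denom if denom > 0 else None
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = sum(_xlog2(v) for v in pdiff.values())
    f["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    f["JointEnergy"] = sum(v * v for v in p.values())
    hxy = sum(_xlog2(v) for v in p.values())
    f["JointEntropy"] = hxy
    hx = sum(_xlog2(v) for v in px.values())
    hy = sum(_xlog2(v) for v in py.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j]) for i in px for j in py
    )
    hmax = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items())
    f["Id"] = sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items())
    f["Idmn"] = sum(v / (1.0 + ((i - j) / ng) ** 2) for (i, j), v in p.items())
    f["Idn"] = sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items())
    f["InverseVariance"] = sum(
        v / (i - j) ** 2 for (i, j), v in p.items() if i != j
    )
    f["MaximumProbability"] = max(p.values())
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = sum(_xlog2(v) for v in psum.values())
    f["SumSquares"] = sum(v * (i - ux) ** 2 for (i, j), v in p.items())

    lev = sorted(px)
    if len(lev) <= 1:
        f["MCC"] = 1.0
    else:
        Q = np.zeros((len(lev), len(lev)))
        for a, i in enumerate(lev):
            for b, j in enumerate(lev):
                Q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                    for k in lev
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        f["MCC"] = math.sqrt(max(0.0, eig[-2]))
    return f


def _average_angles(per_angle):
    """Mean over angles where the feature is defined; None = undefined."""
    keys = None
    for d in per_angle:
        if d is not None:
            keys = d.keys()
            break
    if keys is None:
        return {}
    out = {}
    for k in keys:
        vals = [d[k] for d in per_angle if d is not None and d.get(k) is not None]
        out[k] = sum(vals) / len(vals) if vals else None
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def bf_glrlm(levels, ng, n_pixels, angles=((0, 1), (1, 1), (1, 0), (1, -1))):
    h, w = levels.shape
    per_angle = []
    for (dr, dc) in angles:
        # enumerate line start positions: cells with no valid predecessor
        runs = []
        for r in range(h):
            for c in range(w):
                pr, pc = r - dr, c - dc
                if 0 <= pr < h and 0 <= pc < w:
                    continue  # interior of a line
                # walk the line
                rr, cc = r, c
                current, length = 0, 0
                while 0 <= rr < h and 0 <= cc < w:
                    g = levels[rr, cc]
                    if g != 0 and g == current:
                        length += 1
                    else:
                        if current != 0:
                            runs.append((current, length))
                        current, length = g, (1 if g != 0 else 0)
                    rr += dr
                    cc += dc
                if current != 0:
                    runs.append((current, length))
        per_angle.append(_size_entry_formulas(runs, ng, n_pixels, "run"))
    return _average_angles(per_angle)


def _size_entry_formulas(entries, ng, n_pixels, kind):
    """Shared feature formulas over (level, size) entry lists."""
    if not entries:
        return None
    ns = len(entries)
    P = {}
    for (i, j) in entries:
        P[(i, j)] = P.get((i, j), 0) + 1
    f = {}
    f["SmallEmphasis"] = sum(v / j**2 for (i, j), v in P.items()) / ns
    f["LargeEmphasis"] = sum(v * j**2 for (i, j), v in P.items()) / ns
    f["LowGL"] = sum(v / i**2 for (i, j), v in P.items()) / ns
    f["HighGL"] = sum(v * i**2 for (i, j), v in P.items()) / ns
    f["SmallLow"] = sum(v / (i**2 * j**2) for (i, j), v in P.items()) / ns
    f["SmallHigh"] = sum(v * i**2 / j**2 for (i, j), v in P.items()) / ns
    f["LargeLow"] = sum(v * j**2 / i**2 for (i, j), v in P.items()) / ns
    f["LargeHigh"] = sum(v * i**2 * j**2 for (i, j), v in P.items()) / ns
    sg = {}
    sl = {}
    for (i, j), v in P.items():
        sg[i] = sg.get(i, 0) + v
        sl[j] = sl.get(j, 0) + v
    f["GLN"] = sum(v**2 for v in sg.values()) / ns
    f["GLNN"] = sum(v**2 for v in sg.values()) / ns**2
    f["SizeNonUniformity"] = sum(v**2 for v in sl.values()) / ns
    f["SizeNonUniformityNormalized"] = sum(v**2 for v in sl.values()) / ns**2
    f["Percentage"] = ns / n_pixels
    mu_i = sum(i * v for (i, j), v in P.items()) / ns
    f["GLVariance"] = sum(v * (i - mu_i) ** 2 for (i, j), v in P.items()) / ns
    mu_j = sum(j * v for (i, j), v in P.items()) / ns
    f["SizeVariance"] = sum(v * (j - mu_j) ** 2 for (i, j), v in P.items()) / ns
    f["Entropy"] = sum(_xlog2(v / ns) for v in P.values())
    return f


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def bf_glszm(levels, ng, n_pixels, connectivity=8):
    h, w = levels.shape
    offsets = EIGHT if connectivity == 8 else FOUR
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in offsets:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < h
                        and 0 <= c2 < w
                        and not seen[r2, c2]
                        and levels[r2, c2] == g
                    ):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            zones.append((g, size))
    return _size_entry_formulas(zones, ng, n_pixels, "zone")


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def bf_gldm(levels, ng, n_pixels, alpha=0.0, connectivity=8):
    h, w = levels.shape
    offsets = EIGHT if connectivity == 8 else FOUR
    entries = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            dep = 0
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if (
                    0 <= r2 < h
                    and 0 <= c2 < w
                    and levels[r2, c2] != 0
                    and abs(int(levels[r, c]) - int(levels[r2, c2])) <= alpha
                ):
                    dep += 1
            entries.append((levels[r, c], dep + 1))
    f = _size_entry_formulas(entries, ng, n_pixels, "dependence")
    # the 14-feature dependence catalog has no percentage and no normalized GLN
    f.pop("Percentage", None)
    f.pop("GLNN", None)
    return f


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def bf_ngtdm(levels, ng, connectivity=8):
    h, w = levels.shape
    offsets = EIGHT if connectivity == 8 else FOUR
    ni = {}
    si = {}
    nvp = 0
    for r in range(h):
        for c in range(w):
            g = levels[r, c]
            if g == 0:
                continue
            neigh = [
                levels[r + dr, c + dc]
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w and levels[r + dr, c + dc] != 0
            ]
            if not neigh:
                continue
            nvp += 1
            ni[g] = ni.get(g, 0) + 1
            si[g] = si.get(g, 0.0) + abs(g - sum(neigh) / len(neigh))
    if nvp == 0:
        return None
    pi = {g: n / nvp for g, n in ni.items()}
    lev = sorted(pi)
    ngp = len(lev)
    ssum = sum(si.values())
    psum = sum(pi[g] * si[g] for g in lev)

    f = {}
    f["Coarseness"] = 1.0 / psum if psum > 0 else 1e6
    if ngp > 1:
        pair = sum(
            pi[i] * pi[j] * (i - j) ** 2 for i in lev for j in lev
        ) / (ngp * (ngp - 1))
        f["Contrast"] = pair * ssum / nvp
    else:
        f["Contrast"] = 0.0
    busy_den = sum(abs(i * pi[i] - j * pi[j]) for i in lev for j in lev)
    f["Busyness"] = psum / busy_den if busy_den > 0 else 0.0
    f["Complexity"] = (
        sum(
            abs(i - j) * (pi[i] * si[i] + pi[j] * si[j]) / (pi[i] + pi[j])
            for i in lev
            for j in lev
        )
        / nvp
    )
    strength_num = sum((pi[i] + pi[j]) * (i - j) ** 2 for i in lev for j in lev)
    f["Strength"] = strength_num / ssum if ssum > 0 else 0.0
    return f
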