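"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately loop-based / formula-literal and shares no
code with the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np


def ftv_bruteforce(pe_map: np.ndarray, valid: np.ndarray, voxel_size, threshold: float) -> float:
    count = 0
    for z in range(pe_map.shape[0]):
        for y in range(pe_map.shape[1]):
            for x in range(pe_map.shape[2]):
                if valid[z, y, x] and pe_map[z, y, x] >= threshold:
                    count += 1
    return count * voxel_size[0] * voxel_size[1] * voxel_size[2] / 1000.0


def wf_bruteforce(pe_map, ser_map, ser_valid, roi, pe_thr, ser_thr) -> float:
    num = 0
    den = 0
    for z in range(roi.shape[0]):
        for y in range(roi.shape[1]):
            for x in range(roi.shape[2]):
                if roi[z, y, x]:
                    den += 1
                    if (ser_valid[z, y, x] and pe_map[z, y, x] >= pe_thr
                            and ser_map[z, y, x] >= ser_thr):
                        num += 1
    return num / den


def peak_bruteforce(values, valid, roi, min_valid=14):
    """Exhaustive 3x3x3 window search; returns (best mean, center) or None."""
    nz, ny, nx = values.shape
    best, best_center = None, None
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                if not roi[z, y, x]:
                    continue
                total, k = 0.0, 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if valid[z + dz, y + dy, x + dx]:
                                total += values[z + dz, y + dy, x + dx]
                                k += 1
                if k < min_valid:
                    continue
                m = total / k
                if best is None or m > best:
                    best, best_center = m, (z, y, x)
    return (best, best_center) if best is not None else None


def midranks(x) -> np.ndarray:
    """Average ranks with ties, built from a plain argsort."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> float:
    """Rank-then-Pearson with midrank ties."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def paired_t_bruteforce(pre, post):
    """Textbook t = dbar / (s_d / sqrt(n))."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = len(d)
    dbar = d.sum() / n
    s = np.sqrt(((d - dbar) ** 2).sum() / (n - 1))
    return dbar / (s / np.sqrt(n))


def geomean_normalize_bruteforce(matrix, housekeepers):
    """Per-sample geometric mean of housekeepers, then ratio, then log2."""
    out = matrix.astype(float).copy()
    for sample in matrix.columns:
        prod = 1.0
        for g in housekeepers:
            prod *= matrix.loc[g, sample]
        geo = prod ** (1.0 / len(housekeepers))
        for g in matrix.index:
            out.loc[g, sample] = np.log2(matrix.loc[g, sample] / geo)
    return out


def by_adjust_bruteforce(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up: p * (m/rank) * sum(1/i), monotone, capped."""
    p = np.asarray(pvals, float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        rank = rank_idx + 1
        val = p[order[rank_idx]] * m * c_m / rank
        running = min(running, val)
        adj_sorted[rank_idx] = min(running, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj
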