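"""Brute-force enumeration oracles for the texture-matrix features.

Deliberately naive (explicit python loops, flood fill) and independent of
the package's vectorized implementations: these are the reference the fast
paths are checked against.
"""

from __future__ import annotations

from itertools import product

import numpy as np

OFFSETS_13 = tuple(off for off in product((-1, 0, 1), repeat=3) if off > (0, 0, 0))
OFFSETS_26 = tuple(off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetrized, direction-pooled, normalized co-occurrence matrix."""
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        li = levels[idx]
        for off in OFFSETS_13:
            jdx = tuple(i + distance * o for i, o in zip(idx, off))
            if any(j < 0 or j >= s for j, s in zip(jdx, shape)):
                continue
            if not mask[jdx]:
                continue
            lj = levels[jdx]
            counts[li - 1, lj - 1] += 1
            counts[lj - 1, li - 1] += 1
    return counts / counts.sum()


def brute_glcm_correlation(p: np.ndarray) -> float:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = (i * px).sum()
    muy = (i * py).sum()
    sx = np.sqrt((((i - mux) ** 2) * px).sum())
    sy = np.sqrt((((i - muy) ** 2) * py).sum())
    if sx * sy == 0:
        return 1.0
    acc = 0.0
    for a in range(ng):
        for b in range(ng):
            acc += (a + 1) * (b + 1) * p[a, b]
    return (acc - mux * muy) / (sx * sy)


def brute_glcm_imc1(p: np.ndarray) -> float:
    def h(vals):
        return -sum(v * np.log2(v) for v in np.ravel(vals) if v > 0)

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx, hy, hxy = h(px), h(py), h(p)
    hxy1 = 0.0
    for a in range(p.shape[0]):
        for b in range(p.shape[1]):
            if px[a] * py[b] > 0 and p[a, b] > 0:
                hxy1 -= p[a, b] * np.log2(px[a] * py[b])
            elif px[a] * py[b] > 0:
                hxy1 -= 0.0
    denom = max(hx, hy)
    if denom == 0:
        return 0.0
    return (hxy - hxy1) / denom


def brute_gldm(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence-count matrix (Ng x Nd), Nd = 1 + max neighbors."""
    ng = int(levels[mask].max())
    shape = levels.shape
    records = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        li = levels[idx]
        dep = 0
        for off in OFFSETS_26:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= s for j, s in zip(jdx, shape)):
                continue
            if mask[jdx] and abs(int(levels[jdx]) - int(li)) <= alpha:
                dep += 1
        records.append((li, dep + 1))
    nd = max(r[1] for r in records)
    m = np.zeros((ng, nd))
    for li, j in records:
        m[li - 1, j - 1] += 1
    return m


def brute_gldm_lgle(m: np.ndarray) -> float:
    nz = m.sum()
    acc = 0.0
    for a in range(m.shape[0]):
        for b in range(m.shape[1]):
            acc += m[a, b] / (a + 1) ** 2
    return acc / nz


def brute_glszm(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flood-fill zones of equal level, 26-connectivity, binned by size."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if not mask[idx] or visited[idx]:
            continue
        level = levels[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                jdx = tuple(i + o for i, o in zip(cur, off))
                if any(j < 0 or j >= s for j, s in zip(jdx, shape)):
                    continue
                if mask[jdx] and not visited[jdx] and levels[jdx] == level:
                    visited[jdx] = True
                    stack.append(jdx)
        zones.append((int(level), size))
    ng = int(levels[mask].max())
    ns = max(z[1] for z in zones)
    m = np.zeros((ng, ns))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def brute_glszm_sznn(m: np.ndarray) -> float:
    nz = m.sum()
    return float(sum(m[:, j].sum() ** 2 for j in range(m.shape[1])) / nz**2)


def brute_first_order(values: np.ndarray) -> dict[str, float]:
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    mean = v.sum() / n
    var = ((v - mean) ** 2).sum() / n
    med = (v[(n - 1) // 2] + v[n // 2]) / 2.0
    skew = 0.0
    if var > 0:
        skew = (((v - mean) ** 3).sum() / n) / var**1.5
    return {
        "Maximum": float(v[-1]),
        "Median": float(med),
        "Mean": float(mean),
        "Minimum": float(v[0]),
        "Range": float(v[-1] - v[0]),
        "Variance": float(var),
        "Skewness": float(skew),
        "Energy": float((v**2).sum()),
    }
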