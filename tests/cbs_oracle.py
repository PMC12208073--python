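"""Exhaustive circular-segmentation oracle used by the CBS tests.

Enumerates every admissible arc explicitly through 0/1 arc-mask matrices
(independent of the implementation's cumulative-sum candidate grid) and runs
the full permutation enumeration with the same per-node seeding protocol and
exceedance rule as the implementation.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=64)
def _arc_masks(n: int, min_width: int = 2):
    pairs, rows = [], []
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            m = j - i
            if m < min_width or n - m < min_width:
                continue
            row = np.zeros(n)
            row[i:j] = 1.0
            pairs.append((i, j))
            rows.append(row)
    return np.array(pairs), np.vstack(rows)


def oracle_max_t(x: np.ndarray, min_width: int = 2):
    """Max two-sample t over all arcs, by explicit arc-mask enumeration."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return float("nan"), -1, -1
    pairs, M = _arc_masks(n, min_width)
    m = M.sum(axis=1)
    mc = n - m
    sum_arc = M @ x
    ssq_arc = M @ (x * x)
    sum_c = x.sum() - sum_arc
    ssq_c = (x * x).sum() - ssq_arc
    ss = (ssq_arc - sum_arc**2 / m) + (ssq_c - sum_c**2 / mc)
    ss = np.maximum(ss, 0.0)
    diff = np.abs(sum_arc / m - sum_c / mc)
    denom = np.sqrt(ss / (n - 2) * (1 / m + 1 / mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(t))
    return float(t[best]), int(pairs[best, 0]), int(pairs[best, 1])


def oracle_cbs(x, alpha: float, nperm: int, seed: int):
    """Full-enumeration recursive CBS with the shared permutation protocol."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        node_rng = np.random.default_rng(int(rng.integers(2**31)))
        seg = x[lo:hi]
        if seg.size < 4:
            return
        t_obs, i, j = oracle_max_t(seg)
        if not np.isfinite(t_obs) or i < 0 or np.ptp(seg) == 0:
            return
        exceed = sum(oracle_max_t(node_rng.permutation(seg))[0] >= t_obs - 1e-9
                     for _ in range(nperm))
        if exceed / nperm >= alpha:
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        out.extend(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(out)
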