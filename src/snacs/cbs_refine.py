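"""Round-2 multiplet refinement by circular binary segmentation (CBS).

Multiplets that hide inside a genotype cluster leave a footprint in hash
space: their distance to the cluster's proper-hash centroid changes along the
dendrogram leaf order.  For every hash a centroid (mean CLR expression vector
of the cells in clusters uniquely assigned to that hash) is computed, every
cell's Euclidean distance to each centroid forms an ordered signal within
each cluster, and CBS locates changepoints in those signals.  The superset of
changepoints over hashes subdivides the cluster; narrow segments (at most
``narrow_segment_max`` cells, default 100) are re-evaluated with the
cluster-to-hash rule at a more permissive background percentile (75th instead
of 95th), so a contaminating block of cells can flip to ``multiplet`` (or any
other verdict the rule yields).  Cells outside narrow re-evaluated segments
keep their Round-1 labels.

The segmentation statistic is the circular two-segment t: for each candidate
arc the equal-variance two-sample t between arc and complement, maximized
over all arcs, with significance by permutation.  The permutation loop stops
early only once non-significance is certain (exceedances already above
``alpha * nperm``), which leaves the accept/reject decision identical to full
enumeration.  For signals longer than 512 points the candidate boundaries are
subsampled to a 256-point grid (observed and permuted statistics share the
grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import (DemuxCall, HashExpression, SnacsConfig, FILTERED,
                      RESERVED_LABELS)
from .cluster_assign import ClusterAssignment, cluster_verdict
from .hash_model import BackgroundModel

logger = logging.getLogger("snacs")

_MIN_WIDTH = 2
_FULL_GRID_MAX = 512
_GRID_SIZE = 256


@dataclass
class SegmentationResult:
    cluster_id: str
    hash_id: str
    changepoints: list[int]          # indices into the cluster's leaf-order sequence
    segment_means: list[float] = field(default_factory=list)


def _candidate_boundaries(n: int) -> np.ndarray:
    if n <= _FULL_GRID_MAX:
        return np.arange(n + 1)
    return np.unique(np.round(np.linspace(0, n, _GRID_SIZE + 1)).astype(int))


def _max_circular_t(x: np.ndarray, bounds: np.ndarray,
                    min_width: int = _MIN_WIDTH) -> tuple[float, int, int]:
    """Max over arcs (i, j) of the two-sample t between arc and complement.

    Returns (t_max, i, j) with the arc being x[i:j]; (nan, -1, -1) when no
    admissible arc exists.  Zero pooled variance with differing means maps to
    +inf, with equal means to 0.
    """
    n = x.size
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    i = bounds[:, None].astype(float)
    j = bounds[None, :].astype(float)
    m = j - i
    valid = (m >= min_width) & ((n - m) >= min_width)
    if not valid.any():
        return float("nan"), -1, -1
    Sb, Qb = S[bounds], Q[bounds]
    sum_arc = Sb[None, :] - Sb[:, None]
    ssq_arc = Qb[None, :] - Qb[:, None]
    sum_c = S[n] - sum_arc
    ssq_c = Q[n] - ssq_arc
    with np.errstate(invalid="ignore", divide="ignore"):
        m_safe = np.where(valid, m, 1.0)
        mc_safe = np.where(valid, n - m, 1.0)
        ss_within = (ssq_arc - sum_arc**2 / m_safe) + (ssq_c - sum_c**2 / mc_safe)
        ss_within = np.maximum(ss_within, 0.0)  # guard rounding
        mean_diff = sum_arc / m_safe - sum_c / mc_safe
        pooled = ss_within / max(n - 2, 1)
        denom = np.sqrt(pooled * (1.0 / m_safe + 1.0 / mc_safe))
        t = np.where(denom > 0, np.abs(mean_diff) / np.where(denom > 0, denom, 1.0),
                     np.where(np.abs(mean_diff) > 0, np.inf, 0.0))
    t = np.where(valid, t, -np.inf)
    flat = int(np.argmax(t))
    bi, bj = np.unravel_index(flat, t.shape)
    return float(t[bi, bj]), int(bounds[bi]), int(bounds[bj])


def _split_significant(x: np.ndarray, alpha: float, nperm: int,
                       rng: np.random.Generator,
                       early_stop: bool = True) -> tuple[bool, int, int]:
    """Permutation test for the best circular split of one segment."""
    n = x.size
    bounds = _candidate_boundaries(n)
    t_obs, i, j = _max_circular_t(x, bounds)
    if not np.isfinite(t_obs) or i < 0:
        return False, -1, -1
    if np.ptp(x) == 0:
        return False, -1, -1
    limit = alpha * nperm
    exceed = 0
    for perm in range(nperm):
        t_p, _, _ = _max_circular_t(rng.permutation(x), bounds)
        # tolerance makes exact-tie permutations (e.g. within-segment
        # rearrangements) count as exceedances regardless of float path
        if t_p >= t_obs - 1e-9:
            exceed += 1
            if early_stop and exceed > limit:
                return False, -1, -1
    return (exceed / nperm) < alpha, i, j


def cbs_segment(signal: np.ndarray, alpha: float = 0.01, nperm: int = 1000,
                seed: int | np.random.Generator = 0) -> list[int]:
    """Changepoints of an ordered signal by recursive circular segmentation.

    Returns sorted 0-based indices at which a new segment begins (never 0 or
    ``len(signal)``).  A constant signal yields no changepoints.

    Permutation protocol: every visited segment draws one child seed from the
    master generator (in recursion order, before any significance work), and
    its permutations come from a generator built on that seed.  Early
    stopping therefore never shifts the stream seen by later segments, and
    the changepoint set is a pure function of signal, alpha, nperm and seed.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    changepoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        node_rng = np.random.default_rng(int(rng.integers(2**31)))
        seg = x[lo:hi]
        if seg.size < 2 * _MIN_WIDTH:
            return
        ok, i, j = _split_significant(seg, alpha, nperm, node_rng)
        if not ok:
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        changepoints.extend(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(changepoints)


def hash_centroids(A: ClusterAssignment, E: HashExpression) -> dict[str, np.ndarray]:
    """Mean hash-expression vector per hash over its uniquely assigned clusters."""
    E = E.subset_cells(A.tree.cell_ids)
    centroids: dict[str, np.ndarray] = {}
    for h in E.hash_ids:
        rows = [i for cid, idxs in A.clusters.items()
                if A.verdicts.get(cid) == h for i in idxs]
        if rows:
            centroids[h] = E.values[rows].mean(axis=0)
        else:
            logger.warning("no cluster uniquely assigned to hash %s; "
                           "skipped in refinement", h)
    return centroids


def refine_multiplets(round1: list[DemuxCall], A: ClusterAssignment,
                      E: HashExpression, models: dict[str, BackgroundModel],
                      cfg: SnacsConfig | None = None,
                      seed: int | None = None
                      ) -> tuple[list[DemuxCall], list[SegmentationResult]]:
    """Round-2 calls: re-evaluate narrow CBS segments at the 75th percentile.

    Only clusters in which at least one hash-distance signal has a
    changepoint are subdivided; their segments of at most
    ``cfg.narrow_segment_max`` cells are re-scored with
    :func:`~snacs.cluster_assign.cluster_verdict` using ``cfg.refine_pct``.
    Everything else, including filtered cells, keeps its Round-1 label.
    """
    if cfg is None:
        cfg = SnacsConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    Ein = E.subset_cells(A.tree.cell_ids)
    centroids = hash_centroids(A, Ein)

    labels = {c.cell_id: c.label for c in round1}
    segmentations: list[SegmentationResult] = []

    if centroids:
        cent = np.stack([centroids[h] for h in Ein.hash_ids if h in centroids])
        cent_hashes = [h for h in Ein.hash_ids if h in centroids]
        # cells x centroid-hashes Euclidean distances in full hash space
        diff = Ein.values[:, None, :] - cent[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        for cid, idxs in A.clusters.items():
            cuts: set[int] = set()
            for hj, h in enumerate(cent_hashes):
                cps = cbs_segment(dist[idxs, hj], cfg.cbs_alpha, cfg.cbs_nperm,
                                  seed=rng)
                segmentations.append(SegmentationResult(cid, h, cps))
                cuts.update(cps)
            if not cuts:
                continue
            edges = [0] + sorted(cuts) + [len(idxs)]
            for a, b in zip(edges[:-1], edges[1:]):
                seg_cells = idxs[a:b]
                if len(seg_cells) <= cfg.narrow_segment_max:
                    verdict = cluster_verdict(Ein.values, list(seg_cells),
                                              Ein.hash_ids, models,
                                              cfg.refine_pct,
                                              cfg.cluster_assign_frac)
                    for i in seg_cells:
                        labels[A.tree.cell_ids[i]] = verdict

    return ([DemuxCall(c.cell_id, labels[c.cell_id], "round2") for c in round1],
            segmentations)
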