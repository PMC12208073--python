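"""Imputation, hierarchical clustering and Round-1 sample assignment.

Cells are clustered on the discriminatory SNP panel: missing panel genotypes
are imputed by majority vote of each cell's five nearest neighbours (Hamming
distance over shared observed SNPs), the complete binary matrix is clustered
agglomeratively with cosine distances and Ward linkage, and the dendrogram is
cut into n clusters (n = number of hashes).  Because cells from different
parent samples can share a genotype-defined cluster, each cluster's subtree is
then traversed downward and split whenever any hash antibody separates the two
daughters at an equal-variance t-test p below 1e-5 (daughters below the
minimum cluster size are never created).  Finally each cluster is assigned to
a hash when more than half its cells exceed that hash's background threshold:
one positive hash gives a sample call for every cell in the cluster, several
give ``multiplet``, none give ``no_call``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .core_io import (DemuxCall, GenotypeMatrix, HashExpression, SnacsConfig,
                      MULTIPLET, NO_CALL, ValidationError)
from .hash_model import BackgroundModel

logger = logging.getLogger("snacs")


@dataclass
class ClusterTree:
    cell_ids: list[str]
    linkage: np.ndarray          # scipy linkage matrix
    leaf_order: np.ndarray       # permutation of range(n_cells)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterAssignment:
    """Partition of the clustered cells plus per-cluster hash verdicts."""

    tree: ClusterTree
    clusters: dict[str, list[int]]            # cluster id -> cell indices, leaf order
    verdicts: dict[str, str] = field(default_factory=dict)  # cluster id -> label

    def cluster_of(self) -> dict[int, str]:
        return {i: cid for cid, idxs in self.clusters.items() for i in idxs}


def impute_missing_knn(G_panel: GenotypeMatrix, cfg: SnacsConfig | None = None
                       ) -> tuple[GenotypeMatrix, list[str]]:
    """Fill missing panel genotypes by majority vote of k nearest neighbours.

    Neighbour distance is the Hamming mismatch fraction over panel SNPs
    observed in both cells; the vote at a SNP is taken over the non-missing
    values of the cell's k nearest neighbours, ties and empty votes falling
    back to 0 (wildtype), the conservative call.  Cells missing every panel
    SNP cannot be imputed and are returned separately as filtered.
    """
    if cfg is None:
        cfg = SnacsConfig()
    if G_panel.n_snps == 0:
        raise ValidationError("empty SNP panel")
    V = G_panel.values
    obs = ~np.isnan(V)
    uncallable = ~obs.any(axis=1)
    filtered = [c for c, u in zip(G_panel.cell_ids, uncallable) if u]
    if filtered:
        logger.info("%d cell(s) missing all panel SNPs marked filtered", len(filtered))
        keep = ~uncallable
        V, obs = V[keep], obs[keep]
        cell_ids = [c for c, u in zip(G_panel.cell_ids, uncallable) if not u]
    else:
        cell_ids = list(G_panel.cell_ids)
    if not np.isnan(V).any():
        return GenotypeMatrix(cell_ids, list(G_panel.snp_ids), V.copy()), filtered

    Vo = np.where(obs, V, 0.0).astype(np.float32)
    O = obs.astype(np.float32)
    # pairwise mismatches over shared observed SNPs:
    # mism_ij = sum_s O_i O_j (v_i + v_j - 2 v_i v_j); A = Vo O^T gives both
    # cross terms by symmetry
    A = Vo @ O.T
    dist = A + A.T - 2.0 * (Vo @ Vo.T)
    shared = O @ O.T
    no_overlap = shared == 0
    shared[no_overlap] = 1.0
    dist /= shared
    dist[no_overlap] = np.inf
    np.fill_diagonal(dist, np.inf)

    k = min(cfg.knn_k, len(cell_ids) - 1)
    if k < 1:
        raise ValidationError("not enough cells for kNN imputation")
    nbr = np.argpartition(dist, k - 1, axis=1)[:, :k]
    # order neighbours by distance for determinism
    row = np.arange(len(cell_ids))[:, None]
    nbr = np.take_along_axis(nbr, np.argsort(dist[row, nbr], axis=1, kind="stable"), axis=1)

    out = V.copy()
    miss_cells, miss_snps = np.where(~obs)
    nbr_vals = V[nbr[miss_cells], miss_snps[:, None]]      # missing-entry x k
    ones = np.nansum(nbr_vals == 1.0, axis=1)
    zeros = np.nansum(nbr_vals == 0.0, axis=1)
    out[miss_cells, miss_snps] = (ones > zeros).astype(float)  # ties -> 0
    return GenotypeMatrix(cell_ids, list(G_panel.snp_ids), out), filtered


def _cosine_distances(X: np.ndarray) -> np.ndarray:
    """Condensed cosine distances; all-zero rows get maximal distance 1."""
    d = pdist(X, metric="cosine")
    if np.isnan(d).any():
        d = np.nan_to_num(d, nan=1.0)
    return d


def hierarchical_cluster(M: GenotypeMatrix) -> ClusterTree:
    """Agglomerate the complete binary panel matrix (cosine + Ward)."""
    if M.n_cells < 2:
        raise ValidationError("need at least 2 cells to cluster")
    if np.isnan(M.values).any():
        raise ValidationError("panel matrix must be complete (impute first)")
    Z = hierarchy.linkage(_cosine_distances(M.values), method="ward")
    return ClusterTree(list(M.cell_ids), Z, hierarchy.leaves_list(Z))


def _cut_to_nodes(Z: np.ndarray, n_leaves: int, n: int) -> list:
    """Cut the dendrogram into n clusters, keeping each as a subtree node."""
    root = hierarchy.to_tree(Z)
    nodes = [root]
    while len(nodes) < n:
        splittable = [nd for nd in nodes if not nd.is_leaf()]
        if not splittable:
            raise ValidationError(f"cannot cut into {n} clusters: only "
                                  f"{len(nodes)} leaves available")
        tallest = max(splittable, key=lambda nd: nd.dist)
        nodes.remove(tallest)
        nodes.extend([tallest.get_left(), tallest.get_right()])
    return nodes


def _ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    """Equal-variance two-sample t-test p, with degenerate-case conventions:

    zero variance in both groups -> p = 1 for equal means, p = 0 otherwise.
    """
    if a.size < 1 or b.size < 1:
        return 1.0
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def cut_and_split(tree: ClusterTree, n: int, E: HashExpression,
                  cfg: SnacsConfig | None = None) -> ClusterAssignment:
    """Cut into n clusters, then split subtrees separated by any hash signal.

    A node is replaced by its two daughters when some hash antibody's
    expression differs between the daughters at p < ``cfg.split_pvalue``
    (equal-variance t-test, unadjusted) and both daughters have at least
    ``cfg.min_cluster_size`` cells; the recursion descends into accepted
    daughters and stops elsewhere.
    """
    if cfg is None:
        cfg = SnacsConfig()
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n > tree.n_cells:
        raise ValidationError(f"cannot cut {tree.n_cells} cells into {n} clusters")
    E = E.subset_cells(tree.cell_ids)
    X = E.values

    final_nodes = []

    def descend(node) -> None:
        if node.is_leaf():
            final_nodes.append(node)
            return
        left, right = node.get_left(), node.get_right()
        li, ri = left.pre_order(), right.pre_order()
        if min(len(li), len(ri)) < cfg.min_cluster_size:
            final_nodes.append(node)
            return
        pvals = [_ttest_p(X[li, h], X[ri, h]) for h in range(X.shape[1])]
        if min(pvals) < cfg.split_pvalue:
            descend(left)
            descend(right)
        else:
            final_nodes.append(node)

    for node in _cut_to_nodes(tree.linkage, tree.n_cells, n):
        descend(node)

    pos_in_leaf_order = np.empty(tree.n_cells, dtype=int)
    pos_in_leaf_order[tree.leaf_order] = np.arange(tree.n_cells)
    clusters: dict[str, list[int]] = {}
    # order clusters by their first appearance along the dendrogram leaves
    keyed = sorted(final_nodes, key=lambda nd: min(pos_in_leaf_order[i] for i in nd.pre_order()))
    for ci, node in enumerate(keyed, start=1):
        idxs = sorted(node.pre_order(), key=lambda i: pos_in_leaf_order[i])
        clusters[f"c{ci}"] = idxs
    return ClusterAssignment(tree, clusters)


def cluster_verdict(values: np.ndarray, idxs: list[int], hash_ids: list[str],
                    models: dict[str, BackgroundModel], pct: float,
                    frac: float) -> str:
    """Apply the cluster-to-hash rule to one group of cells.

    Positive for hash h when the fraction of cells strictly above
    ``models[h].q(pct)`` exceeds ``frac``; exactly one positive hash gives the
    hash id, several give ``multiplet``, none ``no_call``.
    """
    positives = []
    for j, h in enumerate(hash_ids):
        thr = models[h].q(pct)
        share = float((values[idxs, j] > thr).mean())
        if share > frac:
            positives.append(h)
    if len(positives) == 1:
        return positives[0]
    return MULTIPLET if positives else NO_CALL


def assign_clusters_to_hashes(A: ClusterAssignment, E: HashExpression,
                              models: dict[str, BackgroundModel],
                              cfg: SnacsConfig | None = None) -> list[DemuxCall]:
    """Round-1 calls: each cluster's verdict propagated to its cells."""
    if cfg is None:
        cfg = SnacsConfig()
    E = E.subset_cells(A.tree.cell_ids)
    calls = []
    for cid, idxs in A.clusters.items():
        verdict = cluster_verdict(E.values, idxs, E.hash_ids, models,
                                  cfg.background_pct, cfg.cluster_assign_frac)
        A.verdicts[cid] = verdict
        for i in idxs:
            calls.append(DemuxCall(A.tree.cell_ids[i], verdict, "round1"))
    return calls
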