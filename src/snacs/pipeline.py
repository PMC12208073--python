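"""End-to-end orchestration of the demultiplexing stages.

``demux_pipeline`` runs: missingness filtering -> CLR normalization ->
per-hash background modelling and preliminary classification -> one-sided
chi-square SNP selection -> kNN imputation, cosine/Ward clustering with
t-test splitting and cluster-to-hash assignment (Round 1) -> optional CBS
refinement (Round 2) -> optional allele-depth doublet combination.  Every
input cell appears in every computed round, filtered cells included.  A
single seed is fanned out to stage-specific generators so stages can be
rerun in isolation.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cbs_refine, cluster_assign, doubletd, hash_model, preprocess, snp_select
from .core_io import (DemuxCall, GenotypeMatrix, HashCounts, HashExpression,
                      SnacsConfig, FILTERED, calls_to_frame)

logger = logging.getLogger("snacs")


@dataclass
class RunManifest:
    config: dict
    seed: int
    n_cells_in: int
    n_snps_in: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    calls: list[DemuxCall]
    filter_report: preprocess.FilterReport
    panel: snp_select.SnpPanel
    tree: cluster_assign.ClusterTree
    assignment: cluster_assign.ClusterAssignment
    models: dict[str, hash_model.BackgroundModel]
    expression: HashExpression
    manifest: RunManifest
    segmentations: list = field(default_factory=list)

    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    def round_labels(self, rnd: str) -> dict[str, str]:
        return {c.cell_id: c.label for c in self.calls if c.round == rnd}

    def final_labels(self) -> dict[str, str]:
        for rnd in ("plus_doubletd", "round2", "round1"):
            labels = self.round_labels(rnd)
            if labels:
                return labels
        return {}


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def demux_pipeline(G: GenotypeMatrix,
                   hashes: HashCounts | HashExpression,
                   cfg: SnacsConfig | None = None,
                   rounds: tuple[int, ...] = (1, 2),
                   allele_depths: "doubletd.AlleleDepthMatrix | None" = None,
                   dd_params: "doubletd.DoubletDParams | None" = None
                   ) -> PipelineResult:
    """Run the demultiplexer on in-memory matrices.

    ``hashes`` may be raw counts (CLR-normalized here) or pre-normalized
    expression.  Requesting round 2 adds CBS refinement; passing
    ``allele_depths`` adds the doublet-combination round.
    """
    if cfg is None:
        cfg = SnacsConfig()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = now - t0
        t0 = now

    if isinstance(hashes, HashCounts):
        E_all = preprocess.clr_normalize(hashes.align_to(G.cell_ids),
                                         cfg.pseudocount)
    else:
        E_all = hashes.subset_cells(G.cell_ids)
    hash_ids = list(E_all.hash_ids)
    n = len(hash_ids)
    tick("normalize")

    G_f, report = preprocess.filter_missingness(G, cfg)
    filtered: list[str] = list(report.removed_cells)
    E = E_all.subset_cells(G_f.cell_ids)
    tick("filter")

    models, prelim = hash_model.fit_background_models(E, cfg)
    tick("background")

    panel = snp_select.rank_discriminatory_snps(G_f, prelim, cfg, hash_ids)
    tick("snp_select")

    M, uncallable = cluster_assign.impute_missing_knn(
        G_f.subset_snps(panel.selected_snp_ids), cfg)
    filtered.extend(uncallable)
    E_m = E.subset_cells(M.cell_ids)
    tick("impute")

    tree = cluster_assign.hierarchical_cluster(M)
    assignment = cluster_assign.cut_and_split(tree, n, E_m, cfg)
    round1 = cluster_assign.assign_clusters_to_hashes(assignment, E_m, models, cfg)
    round1.extend(DemuxCall(c, FILTERED, "round1") for c in filtered)
    calls = list(round1)
    tick("round1")

    segmentations: list = []
    latest = round1
    if 2 in rounds:
        round2, segmentations = cbs_refine.refine_multiplets(
            round1, assignment, E_m, models, cfg, seed=cfg.seed + 1)
        calls.extend(round2)
        latest = round2
        tick("round2")

    if allele_depths is not None:
        dd = doubletd.call_doublets(
            _subset_depths(allele_depths, [c.cell_id for c in latest]),
            dd_params)
        calls.extend(doubletd.combine_calls(
            [DemuxCall(c.cell_id, c.label, "plus_doubletd") for c in latest], dd))
        tick("plus_doubletd")

    manifest = RunManifest(
        config=vars(cfg).copy(), seed=cfg.seed,
        n_cells_in=G.n_cells, n_snps_in=G.n_snps,
        stage_seconds=timings,
        input_digests={"genotype": _digest(G.values),
                       "hash": _digest(E_all.values)},
    )
    return PipelineResult(calls, report, panel, tree, assignment, models,
                          E_m, manifest, segmentations)


def _subset_depths(D: "doubletd.AlleleDepthMatrix", cell_ids: list[str]
                   ) -> "doubletd.AlleleDepthMatrix":
    idx = {c: i for i, c in enumerate(D.cell_ids)}
    missing = [c for c in cell_ids if c not in idx]
    if missing:
        from .core_io import AlignmentError
        raise AlignmentError(f"cells absent from depth matrices: {missing[:5]}")
    rows = [idx[c] for c in cell_ids]
    return doubletd.AlleleDepthMatrix(list(cell_ids), list(D.locus_ids),
                                      D.total_depth[rows], D.alt_depth[rows])


def missing_data_stress(G: GenotypeMatrix,
                        hashes: HashCounts | HashExpression,
                        cfg: SnacsConfig | None = None,
                        grid: tuple[float, ...] = tuple(np.arange(0.0, 0.51, 0.05)),
                        seed: int = 0) -> pd.DataFrame:
    """Degrade genotype observability and track filtering and agreement.

    For each fraction in ``grid``, that share of the observed genotype
    entries is set to missing (seeded), the pipeline is rerun, and the output
    is compared with the intact baseline: the table reports the filtered
    fraction and the agreement (share of input cells whose final label
    matches the baseline's).
    """
    if cfg is None:
        cfg = SnacsConfig()
    rng = np.random.default_rng(seed)
    baseline = demux_pipeline(G, hashes, cfg)
    base_labels = baseline.final_labels()

    rows = []
    obs_i, obs_j = np.where(~G.missing_mask())
    n_obs = obs_i.size
    from .core_io import ValidationError
    for frac in grid:
        if frac == 0.0:
            labels = base_labels
            warning = baseline.filter_report.warning_flag
        else:
            kill = rng.choice(n_obs, size=int(round(frac * n_obs)), replace=False)
            V = G.values.copy()
            V[obs_i[kill], obs_j[kill]] = np.nan
            G_deg = GenotypeMatrix(list(G.cell_ids), list(G.snp_ids), V)
            warning = float(np.isnan(V).mean()) > 0.40
            try:
                result = demux_pipeline(G_deg, hashes, cfg)
            except ValidationError as e:
                # missingness so heavy that nothing survives filtering:
                # tabulate as a fully filtered run rather than aborting
                logger.warning("stress run at %.0f%% removal degenerate: %s",
                               100 * frac, e)
                labels = {c: FILTERED for c in G.cell_ids}
            else:
                labels = result.final_labels()
                warning = result.filter_report.warning_flag
        agree = float(np.mean([labels.get(c) == base_labels.get(c)
                               for c in G.cell_ids]))
        pct_filtered = float(np.mean([labels.get(c) == FILTERED
                                      for c in G.cell_ids]))
        rows.append({"fraction_removed": float(frac),
                     "pct_filtered": pct_filtered,
                     "agreement_with_baseline": agree,
                     "warning": warning})
    return pd.DataFrame(rows)
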