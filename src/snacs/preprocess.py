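"""Missingness filtering and CLR normalization.

Genotype matrices from targeted single-cell DNA panels carry substantial
missingness (failed amplicons, allelic dropout).  SNPs and then cells whose
missing fraction exceeds a threshold (default 40% for both) are removed before
any downstream modelling; removed cells surface in the final calls as
``filtered``.  Hash-antibody counts are normalized with the centered log-ratio
transform taken per antibody across cells: each count (plus a pseudocount) is
divided by the geometric mean of that antibody's counts and log2-transformed,
so every antibody column has mean zero on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import (GenotypeMatrix, HashCounts, HashExpression, SnacsConfig,
                      ValidationError)

logger = logging.getLogger("snacs")


@dataclass
class FilterReport:
    n_snps_in: int
    n_snps_out: int
    n_cells_in: int
    n_cells_out: int
    snp_missing_fraction: dict[str, float]
    cell_missing_fraction: dict[str, float]
    overall_missing_fraction: float
    warning_flag: bool
    removed_cells: list[str]
    removed_snps: list[str]


def filter_missingness(G: GenotypeMatrix, cfg: SnacsConfig | None = None
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs, then cells, whose missing fraction exceeds the thresholds.

    SNP missingness is computed over all input cells; cell missingness over
    the retained SNPs only.  A warning flag is raised when the overall
    missing fraction of the input exceeds 0.40, the regime where accuracy is
    known to degrade.
    """
    if cfg is None:
        cfg = SnacsConfig()
    if G.n_cells == 0 or G.n_snps == 0:
        raise ValidationError("empty genotype matrix")
    miss = G.missing_mask()
    overall = float(miss.mean())
    warn = overall > 0.40
    if warn:
        logger.warning(
            "overall missing fraction %.3f exceeds 0.40; demultiplexing "
            "accuracy degrades in this regime", overall)

    snp_frac = miss.mean(axis=0)
    keep_snps = snp_frac <= cfg.missing_thresh_snp
    if not keep_snps.any():
        raise ValidationError("nothing retained: all SNPs exceed the missingness threshold")

    cell_frac = miss[:, keep_snps].mean(axis=1)
    keep_cells = cell_frac <= cfg.missing_thresh_cell
    if not keep_cells.any():
        raise ValidationError("nothing retained: all cells exceed the missingness threshold")

    out = GenotypeMatrix(
        [c for c, k in zip(G.cell_ids, keep_cells) if k],
        [s for s, k in zip(G.snp_ids, keep_snps) if k],
        G.values[np.ix_(keep_cells, keep_snps)],
    )
    report = FilterReport(
        n_snps_in=G.n_snps, n_snps_out=out.n_snps,
        n_cells_in=G.n_cells, n_cells_out=out.n_cells,
        snp_missing_fraction=dict(zip(G.snp_ids, snp_frac.tolist())),
        cell_missing_fraction=dict(zip(G.cell_ids, cell_frac.tolist())),
        overall_missing_fraction=overall,
        warning_flag=warn,
        removed_cells=[c for c, k in zip(G.cell_ids, keep_cells) if not k],
        removed_snps=[s for s, k in zip(G.snp_ids, keep_snps) if not k],
    )
    logger.info("missingness filter: %d/%d SNPs, %d/%d cells retained",
                out.n_snps, G.n_snps, out.n_cells, G.n_cells)
    return out, report


def clr_normalize(H: HashCounts, pseudocount: float = 1.0) -> HashExpression:
    """Centered log-ratio transform per antibody across cells.

    v_c = log2((x_c + pseudocount) / geomean_cells(x + pseudocount)); each
    column then sums to zero in log space.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if len(H.cell_ids) == 0:
        raise ValidationError("zero cells")
    x = H.counts.astype(float) + pseudocount
    logx = np.log2(x)
    vals = logx - logx.mean(axis=0, keepdims=True)
    return HashExpression(list(H.cell_ids), list(H.hash_ids), vals)
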