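"""Selection of SNPs that discriminate the preliminary hash-defined groups.

For every ordered pair of hash groups (g, g') and every SNP, a 2x2 table of
mutated/wildtype counts is formed from the uniquely hash-classified cells
(missing genotypes excluded per SNP).  The classical Pearson chi-square
statistic ranks the SNPs; one-sidedness is realized as an eligibility filter —
a SNP competes for pair (g, g') only when its mutated proportion in g strictly
exceeds that in g' (the statistic is then the squared one-sided two-proportion
z).  The top k per ordered pair are pooled and deduplicated, giving at most
n(n-1)k panel SNPs.  No continuity correction is applied; degenerate tables
(a zero margin) score 0.  Ties are broken toward larger total counts, then
lexicographic SNP id, so output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import GenotypeMatrix, SnacsConfig, ValidationError
from .hash_model import CellHashCall

logger = logging.getLogger("snacs")


@dataclass
class SnpProvenance:
    snp_id: str
    target_group: str
    other_group: str
    rank: int
    statistic: float
    prop_target: float
    prop_other: float


@dataclass
class SnpPanel:
    selected_snp_ids: list[str]
    provenance: list[SnpProvenance]
    n_groups: int
    k: int

    @property
    def max_size(self) -> int:
        return self.n_groups * (self.n_groups - 1) * self.k


def chi_square_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], no correction.

    Tables with any zero margin get statistic 0 rather than NaN.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0
    return float(n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))


def rank_discriminatory_snps(G: GenotypeMatrix, calls: list[CellHashCall],
                             cfg: SnacsConfig | None = None,
                             hash_ids: list[str] | None = None) -> SnpPanel:
    """Pick the top-k chi-square SNPs for each ordered group pair.

    Only cells uniquely classified to one hash enter the tables.  Raises if
    any expected hash group is empty or fewer than two groups are populated;
    ``hash_ids`` names the full set of expected groups (defaults to the
    hashes observed in the calls).
    """
    if cfg is None:
        cfg = SnacsConfig()
    by_cell = {c.cell_id: c for c in calls}
    groups: dict[str, list[int]] = {}
    for i, cid in enumerate(G.cell_ids):
        call = by_cell.get(cid)
        if call is not None and call.status == "unique":
            groups.setdefault(call.positive_hashes[0], []).append(i)

    expected = hash_ids if hash_ids is not None else \
        sorted({h for c in calls for h in c.positive_hashes})
    empty = [h for h in expected if h not in groups or not groups[h]]
    if empty:
        raise ValidationError(f"hash group(s) with 0 uniquely classified cells: {empty}")
    if len(groups) < 2:
        raise ValidationError("need at least two nonempty hash groups")

    V = G.values
    obs = ~np.isnan(V)
    mut = np.where(obs, V, 0.0)

    # per-group mutated / genotyped counts per SNP
    names = sorted(groups)
    n_mut = {g: mut[groups[g]].sum(axis=0) for g in names}
    n_obs = {g: obs[groups[g]].sum(axis=0).astype(float) for g in names}

    selected: dict[str, None] = {}
    provenance: list[SnpProvenance] = []
    snp_arr = np.array(G.snp_ids)
    for g in names:
        for g2 in names:
            if g == g2:
                continue
            a = n_mut[g]                    # mutated in target
            b = n_obs[g] - n_mut[g]         # wildtype in target
            c = n_mut[g2]
            d = n_obs[g2] - n_mut[g2]
            with np.errstate(invalid="ignore", divide="ignore"):
                p_t = np.where(n_obs[g] > 0, a / n_obs[g], np.nan)
                p_o = np.where(n_obs[g2] > 0, c / n_obs[g2], np.nan)
            eligible = (p_t > p_o) & ~np.isnan(p_t) & ~np.isnan(p_o)
            if not eligible.any():
                logger.warning("no eligible SNP for comparison (%s, %s)", g, g2)
                continue
            n_tot = a + b + c + d
            r1, r2, c1, c2 = a + b, c + d, a + c, b + d
            denom = r1 * r2 * c1 * c2
            with np.errstate(invalid="ignore", divide="ignore"):
                stat = np.where(denom > 0, n_tot * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
            stat = np.where(eligible, stat, -np.inf)
            # order: statistic desc, total count desc, snp id asc
            idx = np.arange(G.n_snps)
            order = sorted(idx[eligible],
                           key=lambda j: (-stat[j], -n_tot[j], snp_arr[j]))
            for rank, j in enumerate(order[: cfg.k_top_snps], start=1):
                sid = str(snp_arr[j])
                selected.setdefault(sid, None)
                provenance.append(SnpProvenance(
                    sid, g, g2, rank, float(stat[j]),
                    float(p_t[j]), float(p_o[j])))

    panel = SnpPanel(list(selected), provenance, n_groups=len(names), k=cfg.k_top_snps)
    logger.info("SNP panel: %d unique SNPs (bound %d) from %d groups",
                len(panel.selected_snp_ids), panel.max_size, len(names))
    return panel


def write_panel(panel: SnpPanel, path) -> None:
    import pandas as pd
    rows = [(p.snp_id, p.target_group, p.other_group, p.rank, p.statistic,
             p.prop_target, p.prop_other) for p in panel.provenance]
    pd.DataFrame(rows, columns=["snp_id", "target_group", "other_group",
                                "rank", "statistic", "prop_target",
                                "prop_other"]).to_csv(path, sep="\t", index=False)
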