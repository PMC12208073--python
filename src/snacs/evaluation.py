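"""Truth calling against single-sample references, and accuracy metrics.

When the samples pooled in a multiplexed run were also sequenced one at a
time, those single-sample experiments define per-sample SNP profiles (a SNP
is "present" when observed mutated in more than 0.5% of that sample's cells,
and counts only if adequately genotyped in every reference).  Each
multiplexed cell is then matched against these profiles: an exact match to
one sample that conflicts with every other and is not explainable as a
combination of samples is a true singlet; a profile that is exactly the union
of two or more samples' profiles is a true multiplet; anything else —
including a mutated SNP that no reference adequately genotyped — is
ambiguous.  The metrics mirror the standard confusion-table quantities over
cells that are neither filtered by the demultiplexer nor ambiguous by truth.
"""

from __future__ import annotations

import logging
import itertools
from dataclasses import dataclass

import numpy as np

from .core_io import (DemuxCall, GenotypeMatrix, ValidationError, MULTIPLET,
                      NO_CALL, FILTERED)

logger = logging.getLogger("snacs")

SINGLET = "singlet"
AMBIGUOUS = "ambiguous"


@dataclass
class TruthCall:
    cell_id: str
    kind: str                 # "singlet" | "multiplet" | "ambiguous"
    sample: str | None = None  # hash/sample id for singlets

    def __post_init__(self) -> None:
        if self.kind not in (SINGLET, MULTIPLET, AMBIGUOUS):
            raise ValidationError(f"unknown truth kind {self.kind!r}")
        if self.kind == SINGLET and self.sample is None:
            raise ValidationError("singlet truth requires a sample id")


@dataclass
class ReferenceProfiles:
    sample_ids: list[str]
    snp_ids: list[str]                 # SNPs genotyped in every reference
    present: np.ndarray                # samples x shared SNPs boolean
    prevalence_thresh: float = 0.005

    def profile(self, sample: str) -> np.ndarray:
        return self.present[self.sample_ids.index(sample)]


def build_reference_profiles(single_sample_Gs: dict[str, GenotypeMatrix],
                             prevalence_thresh: float = 0.005,
                             genotyped_frac: float = 0.6) -> ReferenceProfiles:
    """Present-SNP sets per sample over the SNPs genotyped in all references.

    A SNP is adequately genotyped in a reference when non-missing in at least
    ``genotyped_frac`` of its cells, and present when mutated in more than
    ``prevalence_thresh`` of the cells genotyped there.
    """
    if len(single_sample_Gs) < 2:
        raise ValidationError("need at least two single-sample references")
    samples = list(single_sample_Gs)
    for s, G in single_sample_Gs.items():
        if G.n_cells == 0:
            raise ValidationError(f"empty reference sample {s!r}")

    shared: list[str] | None = None
    genotyped_by_sample = {}
    for s, G in single_sample_Gs.items():
        obs_frac = (~G.missing_mask()).mean(axis=0)
        genotyped = {snp for snp, f in zip(G.snp_ids, obs_frac)
                     if f >= genotyped_frac}
        genotyped_by_sample[s] = genotyped
        shared = genotyped if shared is None else {x for x in shared if x in genotyped}
    shared_snps = sorted(shared or [])

    present = np.zeros((len(samples), len(shared_snps)), dtype=bool)
    for si, s in enumerate(samples):
        G = single_sample_Gs[s]
        col = {snp: j for j, snp in enumerate(G.snp_ids)}
        for sj, snp in enumerate(shared_snps):
            v = G.values[:, col[snp]]
            obs = v[~np.isnan(v)]
            if obs.size:
                present[si, sj] = (obs == 1).mean() > prevalence_thresh
    return ReferenceProfiles(samples, shared_snps, present, prevalence_thresh)


def truth_call_cell(genotype: dict[str, float] | "np.ndarray",
                    refs: ReferenceProfiles, cell_id: str = "",
                    snp_ids: list[str] | None = None,
                    max_subset: int = 2) -> TruthCall:
    """Label one multiplexed cell singlet / multiplet / ambiguous.

    ``genotype`` maps SNP id to 0/1/NaN (or is an array aligned to
    ``snp_ids``).  Rules, applied to the cell's non-missing SNPs:

    * any mutated SNP outside the reference comparison set -> ambiguous;
    * singlet(s): matches sample s exactly (positives and negatives),
      conflicts with every other sample in at least one SNP, and is not
      exactly the union of any 2..``max_subset`` samples' profiles;
    * multiplet: not a singlet, but exactly some such union;
    * otherwise ambiguous.
    """
    if snp_ids is not None:
        genotype = dict(zip(snp_ids, np.asarray(genotype, dtype=float)))
    shared_index = {snp: j for j, snp in enumerate(refs.snp_ids)}

    for snp, v in genotype.items():
        if v == 1 and snp not in shared_index:
            return TruthCall(cell_id, AMBIGUOUS)

    obs_cols, obs_vals = [], []
    for snp, v in genotype.items():
        if snp in shared_index and not np.isnan(v):
            obs_cols.append(shared_index[snp])
            obs_vals.append(bool(v))
    if not obs_cols:
        return TruthCall(cell_id, AMBIGUOUS)
    cols = np.array(obs_cols)
    g = np.array(obs_vals)

    P = refs.present[:, cols]
    matches = (P == g[None, :]).all(axis=1)

    union_match_subsets = []
    for r in range(2, min(max_subset, len(refs.sample_ids)) + 1):
        for combo in itertools.combinations(range(len(refs.sample_ids)), r):
            union = P[list(combo)].any(axis=0)
            if (union == g).all():
                union_match_subsets.append(combo)

    match_idx = np.flatnonzero(matches)
    if match_idx.size == 1 and not union_match_subsets:
        # exact match to one sample, conflict with all others, no union
        return TruthCall(cell_id, SINGLET, refs.sample_ids[int(match_idx[0])])
    if union_match_subsets:
        return TruthCall(cell_id, MULTIPLET)
    return TruthCall(cell_id, AMBIGUOUS)


def truth_calls_for_matrix(G: GenotypeMatrix, refs: ReferenceProfiles,
                           max_subset: int = 2) -> list[TruthCall]:
    return [truth_call_cell(dict(zip(G.snp_ids, G.values[i])), refs,
                            cell_id=cid, max_subset=max_subset)
            for i, cid in enumerate(G.cell_ids)]


@dataclass
class MetricsReport:
    total_accuracy: float
    sensitivity: float
    specificity: float
    alt_singlet_fraction: float
    pct_filtered: float
    n_true_singlets: int
    n_true_multiplets: int
    n_evaluated: int

    def as_dict(self) -> dict:
        return {
            "total_accuracy": self.total_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "alt_singlet_fraction": self.alt_singlet_fraction,
            "pct_filtered": self.pct_filtered,
            "n_true_singlets": self.n_true_singlets,
            "n_true_multiplets": self.n_true_multiplets,
            "n_evaluated": self.n_evaluated,
        }


def score_demux(calls: list[DemuxCall], truths: list[TruthCall]) -> MetricsReport:
    """Accuracy / multiplet sensitivity / singlet specificity of a call set.

    Evaluated cells are those neither filtered by the demultiplexer nor
    ambiguous by truth.  A sample call is correct when the truth is a singlet
    of that sample; a multiplet call when the truth is a multiplet; ``no_call``
    is never correct.  Sensitivity is called-multiplet among true multiplets,
    specificity called-singlet (any sample) among true singlets, and the
    alternative-singlet fraction is, among sample-called cells with singlet
    truth, the share assigned to the wrong sample.
    """
    truth_by_cell = {t.cell_id: t for t in truths}
    missing = [c.cell_id for c in calls if c.cell_id not in truth_by_cell]
    if missing:
        raise ValidationError(f"cells without truth calls: {missing[:5]}")

    n_total = len(calls)
    n_filtered = sum(1 for c in calls if c.label == FILTERED)
    n_correct = n_eval = 0
    n_true_singlet = n_true_multiplet = 0
    n_called_multiplet_true_multiplet = 0
    n_called_singlet_true_singlet = 0
    n_singlet_calls_on_singlets = n_alt = 0

    for c in calls:
        t = truth_by_cell[c.cell_id]
        if c.label == FILTERED or t.kind == AMBIGUOUS:
            continue
        n_eval += 1
        is_sample_call = c.label not in (MULTIPLET, NO_CALL, FILTERED)
        if t.kind == SINGLET:
            n_true_singlet += 1
            if is_sample_call:
                n_called_singlet_true_singlet += 1
                n_singlet_calls_on_singlets += 1
                if c.label == t.sample:
                    n_correct += 1
                else:
                    n_alt += 1
        else:  # true multiplet
            n_true_multiplet += 1
            if c.label == MULTIPLET:
                n_called_multiplet_true_multiplet += 1
                n_correct += 1

    if n_eval == 0:
        logger.warning("empty evaluation set: all cells filtered or ambiguous")
        nan = float("nan")
        return MetricsReport(nan, nan, nan, nan,
                             n_filtered / n_total if n_total else nan,
                             0, 0, 0)

    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return MetricsReport(
        total_accuracy=n_correct / n_eval,
        sensitivity=_rate(n_called_multiplet_true_multiplet, n_true_multiplet),
        specificity=_rate(n_called_singlet_true_singlet, n_true_singlet),
        alt_singlet_fraction=_rate(n_alt, n_singlet_calls_on_singlets),
        pct_filtered=n_filtered / n_total,
        n_true_singlets=n_true_singlet,
        n_true_multiplets=n_true_multiplet,
        n_evaluated=n_eval,
    )
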