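"""Allele-depth doublet detection and combination with the demultiplexer.

A doublet merges the DNA of two cells, so its variant allele frequencies
(VAFs) concentrate near mixture values (0.25, 0.75, ...) instead of the
singlet values (~0, 0.5, ~1), and allelic dropout (ADO) further perturbs
heterozygous sites.  Each cell's alternate/total depth profile is scored
under a singlet and a doublet emission model — beta-binomial mixtures over
the respective VAF states, with ADO smearing the heterozygous state toward
the homozygous extremes — and an EM over the cell-level doublet indicators
updates the doublet prior until the per-cell posteriors stabilise.  A cell
with posterior above the decision threshold is a doublet.

The final combination rule is a logical OR: a cell is a multiplet when the
cluster-based demultiplexer or the allele-depth model says so; otherwise the
demultiplexer's label stands.  Cells the demultiplexer filtered stay
filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import betabinom
from scipy.special import logsumexp

from .core_io import DemuxCall, ValidationError, MULTIPLET, FILTERED

logger = logging.getLogger("snacs")


@dataclass
class AlleleDepthMatrix:
    cell_ids: list[str]
    locus_ids: list[str]
    total_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.total_depth = np.asarray(self.total_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        shape = (len(self.cell_ids), len(self.locus_ids))
        if self.total_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValidationError("depth matrix shapes inconsistent with id lists")
        if (self.total_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValidationError("depths must be nonnegative")
        if (self.alt_depth > self.total_depth).any():
            raise ValidationError("alt depth exceeds total depth")


@dataclass
class DoubletCall:
    cell_id: str
    posterior_doublet: float
    is_doublet: bool


@dataclass
class DoubletDParams:
    doublet_prior: float = 0.1
    ado_rate: float = 0.05
    seq_error_rate: float = 0.01
    overdispersion: float = 50.0   # beta-binomial precision
    threshold: float = 0.5
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.doublet_prior < 1.0:
            raise ValidationError("doublet_prior must lie in (0, 1)")
        for name in ("ado_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValidationError(f"{name}={v} out of range [0, 0.5)")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion must be positive")


def _state_loglik(alt: np.ndarray, tot: np.ndarray, means: np.ndarray,
                  weights: np.ndarray, tau: float) -> np.ndarray:
    """Per-cell log-likelihood under a beta-binomial VAF-state mixture.

    Loci with zero total depth contribute nothing.
    """
    n_cells, n_loci = alt.shape
    lp = np.full((n_cells, n_loci, means.size), -np.inf)
    covered = tot > 0
    a = means * tau
    b = (1.0 - means) * tau
    for s in range(means.size):
        lp[..., s] = np.where(
            covered,
            betabinom.logpmf(alt, np.maximum(tot, 1), a[s], b[s]),
            0.0,
        )
    locus_ll = logsumexp(lp + np.log(weights)[None, None, :], axis=2)
    locus_ll = np.where(covered, locus_ll, 0.0)
    return locus_ll.sum(axis=1)


def call_doublets(D: AlleleDepthMatrix,
                  params: DoubletDParams | None = None) -> list[DoubletCall]:
    """EM doublet posteriors from total/alternate allele-depth matrices.

    Singlet VAF states are {eps, 0.5, 1-eps} with the heterozygous state
    smeared by the ADO rate toward the extremes; doublet states add the
    mixture VAFs {0.25, 0.75}.  The EM updates the doublet prior; emission
    rates are fixed at their configured values.
    """
    if params is None:
        params = DoubletDParams()
    if len(D.cell_ids) == 0 or len(D.locus_ids) == 0:
        raise ValidationError("empty allele-depth matrix")
    if not (D.total_depth > 0).any():
        raise ValidationError("all-zero depths")

    eps = params.seq_error_rate
    ado = params.ado_rate
    # singlet: hom-ref, het (with ADO spill to the extremes), hom-alt
    s_means = np.array([eps, 0.5, 1.0 - eps])
    s_weights = np.array([1.0 / 3 + ado / 6, (1.0 - ado) / 3, 1.0 / 3 + ado / 6])
    # doublet: adds the two-cell mixture VAFs
    d_means = np.array([eps, 0.25, 0.5, 0.75, 1.0 - eps])
    d_weights = np.full(5, 0.2)

    ll_s = _state_loglik(D.alt_depth, D.total_depth, s_means, s_weights,
                         params.overdispersion)
    ll_d = _state_loglik(D.alt_depth, D.total_depth, d_means, d_weights,
                         params.overdispersion)

    pi = params.doublet_prior
    post = np.full(len(D.cell_ids), pi)
    converged = False
    for _ in range(params.max_iter):
        log_num = np.log(pi) + ll_d
        log_den = np.logaddexp(np.log1p(-pi) + ll_s, log_num)
        new_post = np.exp(log_num - log_den)
        new_pi = float(np.clip(new_post.mean(), 1e-6, 1.0 - 1e-6))
        if np.abs(new_post - post).max() < params.tol:
            post, pi = new_post, new_pi
            converged = True
            break
        post, pi = new_post, new_pi
    if not converged:
        logger.warning("doublet EM did not converge in %d iterations; "
                       "using last iterate", params.max_iter)

    return [DoubletCall(cid, float(p), bool(p > params.threshold))
            for cid, p in zip(D.cell_ids, post)]


def combine_calls(snacs_calls: list[DemuxCall],
                  dd_calls: list[DoubletCall]) -> list[DemuxCall]:
    """OR-combine demultiplexer and doublet calls (round ``plus_doubletd``).

    A cell is a multiplet when either caller flags it; otherwise the
    demultiplexer's label stands.  Filtered cells remain filtered.  The two
    inputs must cover the same cells.
    """
    dd_by_cell = {c.cell_id: c for c in dd_calls}
    snacs_ids = {c.cell_id for c in snacs_calls}
    if snacs_ids != set(dd_by_cell):
        only_snacs = sorted(snacs_ids - set(dd_by_cell))[:5]
        only_dd = sorted(set(dd_by_cell) - snacs_ids)[:5]
        raise ValidationError(
            f"cell universes differ (demux-only: {only_snacs}, "
            f"doubletd-only: {only_dd})")
    out = []
    for c in snacs_calls:
        if c.label == FILTERED:
            label = FILTERED
        elif c.label == MULTIPLET or dd_by_cell[c.cell_id].is_doublet:
            label = MULTIPLET
        else:
            label = c.label
        out.append(DemuxCall(c.cell_id, label, "plus_doubletd"))
    return out
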