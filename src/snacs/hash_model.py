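"""Per-hash background modelling and initial cell classification.

In a multiplexed experiment each hash antibody's CLR expression is bimodal:
a left mode of unstained cells (cells from the other parent samples) and a
right mode of stained cells.  The background (unstained) distribution is
estimated nonparametrically: locate the two modes by Gaussian KDE, then build
a symmetric background sample by reflecting all values at or below the left
mode about that mode.  A cell is called positive for a hash when its
expression strictly exceeds a high percentile (default 95th) of that
background sample.

If the KDE does not show exactly two modes at the Silverman bandwidth, the
bandwidth is adapted in 25% steps — shrunk while fewer than two modes are
visible, widened while more than two are — until exactly two remain.  When a
hash ends up with fewer than ``min_cells_per_hash`` uniquely assigned cells,
a rank-based fallback re-estimates that hash's background from the lower half
of its values, which is robust when the stained mode is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import HashExpression, SnacsConfig, ValidationError

logger = logging.getLogger("snacs")

_GRID_POINTS = 512
_MAX_ADAPT_STEPS = 30
_MIN_VALUES = 20


@dataclass
class BackgroundModel:
    """Reflected background sample for one hash antibody."""

    hash_id: str
    left_mode: float
    reflected_sample: np.ndarray
    bandwidth_used: float
    n_modes_found_initially: int
    bandwidth_trajectory: list[float] = field(default_factory=list)
    method: str = "kde"  # "kde" or "robust"

    def q(self, pct: float) -> float:
        """Empirical percentile of the reflected background sample."""
        return float(np.percentile(self.reflected_sample, pct))


@dataclass
class CellHashCall:
    cell_id: str
    positive_hashes: list[str]
    status: str  # "unique", "multiple", "none"

    @property
    def unique_hash(self) -> str | None:
        return self.positive_hashes[0] if self.status == "unique" else None


def _kde_modes(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Locations of strict local maxima of the KDE on a 512-point grid."""
    kde = stats.gaussian_kde(values, bw_method=bandwidth / values.std(ddof=1))
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, _GRID_POINTS)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    return grid[1:-1][interior]


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def _reflect(values: np.ndarray, mode: float) -> np.ndarray:
    left = values[values <= mode]
    return np.concatenate([left, 2.0 * mode - left])


def estimate_background(values: np.ndarray, cfg: SnacsConfig | None = None,
                        hash_id: str = "") -> BackgroundModel:
    """Estimate one hash's background distribution by mode reflection.

    Raises if fewer than 20 values are supplied, if the values are
    degenerate, or if no two-mode KDE configuration is found within 30
    bandwidth-adaptation steps.
    """
    if cfg is None:
        cfg = SnacsConfig()
    values = np.asarray(values, dtype=float)
    if values.size < _MIN_VALUES:
        raise ValidationError(
            f"too few cells ({values.size}) to model hash background")
    if np.ptp(values) == 0:
        raise ValidationError("degenerate hash values: all equal")

    bw = _silverman_bandwidth(values)
    trajectory = []
    n_initial = None
    for _ in range(_MAX_ADAPT_STEPS):
        trajectory.append(bw)
        modes = _kde_modes(values, bw)
        if n_initial is None:
            n_initial = len(modes)
        if len(modes) == 2:
            left_mode = float(modes.min())
            return BackgroundModel(
                hash_id=hash_id, left_mode=left_mode,
                reflected_sample=_reflect(values, left_mode),
                bandwidth_used=bw, n_modes_found_initially=n_initial,
                bandwidth_trajectory=trajectory)
        # shrinking the bandwidth can only add modes, widening only remove
        # them, so step toward two from either side
        bw = bw * (1.0 - cfg.bandwidth_step) if len(modes) < 2 \
            else bw * (1.0 + cfg.bandwidth_step)
    raise ValidationError(
        f"background not bimodal for hash {hash_id!r}: no two-mode "
        f"configuration within {_MAX_ADAPT_STEPS} bandwidth steps")


def robust_fallback(values: np.ndarray, cfg: SnacsConfig | None = None,
                    hash_id: str = "") -> BackgroundModel:
    """Rank-based background estimate for hashes with few stained cells.

    The left mode is taken as the median of the lower half of the values and
    the reflected background is built from values at or below it.  Used when
    the KDE route assigns fewer than ``min_cells_per_hash`` cells uniquely to
    a hash (a small stained mode distorts the KDE mode geometry).
    """
    values = np.asarray(values, dtype=float)
    if values.size < _MIN_VALUES:
        raise ValidationError(
            f"too few cells ({values.size}) to model hash background")
    lower_half = np.sort(values)[: max(2, values.size // 2)]
    mode = float(np.median(lower_half))
    return BackgroundModel(
        hash_id=hash_id, left_mode=mode,
        reflected_sample=_reflect(values, mode),
        bandwidth_used=float("nan"), n_modes_found_initially=-1,
        method="robust")


def classify_cells_by_hash(E: HashExpression,
                           models: dict[str, BackgroundModel],
                           pct: float = 95.0) -> list[CellHashCall]:
    """Call each cell positive for every hash whose threshold it exceeds.

    A cell's value must strictly exceed the ``pct`` percentile of the hash's
    reflected background; ties are negative.  Status is ``unique`` for
    exactly one positive hash, ``multiple`` for several, ``none`` for none.
    """
    missing = [h for h in E.hash_ids if h not in models]
    if missing:
        raise ValidationError(f"no background model for hashes: {missing}")
    thresholds = np.array([models[h].q(pct) for h in E.hash_ids])
    positive = E.values > thresholds[None, :]
    calls = []
    for i, cid in enumerate(E.cell_ids):
        pos = [h for h, p in zip(E.hash_ids, positive[i]) if p]
        status = "unique" if len(pos) == 1 else ("multiple" if pos else "none")
        calls.append(CellHashCall(cid, pos, status))
    return calls


def fit_background_models(E: HashExpression, cfg: SnacsConfig | None = None
                          ) -> tuple[dict[str, BackgroundModel], list[CellHashCall]]:
    """Fit all per-hash backgrounds, applying the small-sample fallback.

    After the initial KDE fit and classification, any hash with fewer than
    ``cfg.min_cells_per_hash`` uniquely assigned cells is re-estimated with
    :func:`robust_fallback` and all cells are reclassified.  If the fallback
    still yields too few cells a warning is logged (small samples are
    legitimate).
    """
    if cfg is None:
        cfg = SnacsConfig()
    models: dict[str, BackgroundModel] = {}
    for h in E.hash_ids:
        col = E.column(h)
        try:
            models[h] = estimate_background(col, cfg, hash_id=h)
        except ValidationError as e:
            logger.warning("KDE background failed for hash %s (%s); "
                           "using robust fallback", h, e)
            models[h] = robust_fallback(col, cfg, hash_id=h)

    calls = classify_cells_by_hash(E, models, cfg.background_pct)
    counts = _unique_counts(calls, E.hash_ids)
    low = [h for h in E.hash_ids if counts[h] < cfg.min_cells_per_hash]
    if low:
        for h in low:
            if models[h].method != "robust":
                logger.info("hash %s has %d < %d uniquely assigned cells; "
                            "re-estimating background robustly",
                            h, counts[h], cfg.min_cells_per_hash)
                models[h] = robust_fallback(E.column(h), cfg, hash_id=h)
        calls = classify_cells_by_hash(E, models, cfg.background_pct)
        counts = _unique_counts(calls, E.hash_ids)
        still_low = [h for h in E.hash_ids if counts[h] < cfg.min_cells_per_hash]
        for h in still_low:
            logger.warning("hash %s still has %d < %d uniquely assigned "
                           "cells after fallback", h, counts[h],
                           cfg.min_cells_per_hash)
    return models, calls


def _unique_counts(calls: list[CellHashCall], hash_ids: list[str]) -> dict[str, int]:
    counts = {h: 0 for h in hash_ids}
    for c in calls:
        if c.status == "unique":
            counts[c.positive_hashes[0]] += 1
    return counts
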