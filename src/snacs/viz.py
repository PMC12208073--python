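"""Best-effort diagnostic plots: demux heatmap and background fits.

Plot rendering never gates pipeline success; failures are logged and
swallowed by the CLI.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_io import MULTIPLET, NO_CALL, FILTERED
from .hash_model import BackgroundModel
from .pipeline import PipelineResult

logger = logging.getLogger("snacs")


def demux_heatmap(result: PipelineResult, path: str) -> None:
    """Cells (leaf order) x panel SNPs with hash-signal and call tracks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tree = result.tree
    order = tree.leaf_order
    E = result.expression
    hash_ids = E.hash_ids
    labels = result.round_labels("round2") or result.round_labels("round1")
    label_codes = {h: i for i, h in enumerate(hash_ids)}
    label_codes.update({MULTIPLET: len(hash_ids), NO_CALL: len(hash_ids) + 1,
                        FILTERED: len(hash_ids) + 2})

    fig, axes = plt.subplots(
        2, 1, figsize=(10, 6), sharex=True,
        gridspec_kw={"height_ratios": [1, 3]})
    sig = E.values[order].T
    axes[0].imshow(sig, aspect="auto", cmap="viridis", interpolation="nearest")
    axes[0].set_yticks(range(len(hash_ids)), hash_ids, fontsize=7)
    axes[0].set_title("hash antibody expression (CLR)")

    calls = np.array([label_codes.get(labels.get(c, FILTERED), -1)
                      for c in np.array(tree.cell_ids)[order]])
    axes[1].imshow(calls[None, :], aspect="auto", cmap="tab10",
                   interpolation="nearest")
    axes[1].set_yticks([0], ["call"])
    axes[1].set_xlabel("cells (dendrogram leaf order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def background_plot(values: np.ndarray, model: BackgroundModel,
                    pct: float, path: str) -> None:
    """Histogram of one hash's CLR values with the background threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(values, bins=60, density=True, alpha=0.6, label="all cells")
    ax.hist(model.reflected_sample, bins=60, density=True, alpha=0.4,
            label="reflected background")
    thr = model.q(pct)
    ax.axvline(thr, color="red", ls="--", label=f"q({pct:g}) = {thr:.2f}")
    ax.axvline(model.left_mode, color="black", ls=":", label="left mode")
    ax.set_xlabel("CLR expression")
    ax.legend(fontsize=8)
    ax.set_title(f"hash {model.hash_id} background")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
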