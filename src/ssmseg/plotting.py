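"""Optional matplotlib rendering of the SSM with aligned curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_ssm", "plot_dendrogram"]


def plot_ssm(ssm, novelty=None, similarity=None, events=None, truth_samples=None, path=None):
    """Render the SSM heat map with the novelty and/or similarity curve below.

    ``events`` (an EventSet) and ``truth_samples`` (sample indices) are
    drawn as markers/dashed lines on the curve panel.
    """
    n_rows = 1 + (novelty is not None) + (similarity is not None)
    ratios = [4] + [1] * (n_rows - 1)
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(6, 6 + n_rows), sharex=True, height_ratios=ratios
    )
    axes = np.atleast_1d(axes)
    axes[0].imshow(ssm.values, origin="lower", cmap="viridis", aspect="auto")
    axes[0].set_ylabel("frame")
    row = 1
    for curve, name in ((novelty, "novelty"), (similarity, "similarity")):
        if curve is None:
            continue
        ax = axes[row]
        ax.plot(curve.values, lw=0.8)
        ax.set_ylabel(name)
        if events is not None and events.event_type.startswith(name[:4]):
            ax.plot(events.frame_indices, events.scores, "ro", ms=4)
        if truth_samples is not None:
            starts = ssm.window_starts
            w2 = ssm.config.w // 2
            for s in truth_samples:
                f = int(np.argmin(np.abs(starts + w2 - s)))
                ax.axvline(f, color="k", ls="--", lw=0.6)
        row += 1
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_dendrogram(tree, labels=None, path=None):
    """Draw the agglomerative merge tree of segment profiles."""
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(5, 4))
    hierarchy.dendrogram(tree, labels=labels, ax=ax)
    ax.set_ylabel("Euclidean profile distance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
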