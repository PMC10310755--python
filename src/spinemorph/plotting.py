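"""Small matplotlib helpers for the standard pipeline figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_quality_curve(curve, selected=None, ax=None):
    """Criterion score vs parameter grid, with the selected value marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.scores, "o-")
    if selected is not None:
        ax.axvline(selected, color="r", ls="--", label=f"selected = {selected}")
        ax.legend()
    ax.set_xlabel("parameter")
    ax.set_ylabel(curve.criterion)
    return ax


def plot_projection(coords, labels=None, ax=None):
    """2D PCA/t-SNE map colored by class or cluster labels."""
    coords = np.asarray(coords)
    if ax is None:
        _, ax = plt.subplots()
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=12, label=str(lab))
        ax.legend(fontsize=8)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    return ax


def plot_cldh(hist, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    bins = np.asarray(hist.bins)
    edges = np.linspace(0, 1, len(bins) + 1)
    ax.bar(edges[:-1], bins, width=np.diff(edges), align="edge")
    ax.set_xlabel("normalized chord length")
    ax.set_ylabel("probability")
    return ax
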