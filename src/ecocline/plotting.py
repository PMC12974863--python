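"""Basic diagnostic renders: LD decay curve, scree plot, LD heatmap."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ld_decay(decay, ax=None):
    """Log-log mean R^2 vs pair distance."""
    ax = _axes(ax)
    ax.plot(decay["bin_bp"], decay["mean_r2"], lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("pair distance (bp)")
    ax.set_ylabel("mean $R^2$")
    return ax


def plot_scree(pve, ax=None):
    ax = _axes(ax)
    pve = np.asarray(pve)
    ax.bar(np.arange(1, pve.size + 1), 100 * pve)
    ax.set_xlabel("principal component")
    ax.set_ylabel("variance explained (%)")
    return ax


def plot_ld_heatmap(summary, ax=None):
    """High-loading variant R^2 matrix, rows ordered by block label."""
    ax = _axes(ax)
    order = (
        np.argsort(summary.blocks, kind="stable")
        if summary.blocks is not None
        else np.arange(summary.r2_matrix.shape[0])
    )
    im = ax.imshow(summary.r2_matrix[np.ix_(order, order)], vmin=0, vmax=1, cmap="Reds")
    ax.figure.colorbar(im, ax=ax, label="$R^2$")
    ax.set_xlabel("variant")
    ax.set_ylabel("variant")
    return ax
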