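"""Plots for fitted results (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np


def plot_global_curves(results, path=None):
    """Group-mean +/- SD curves of the seven global metrics vs sparsity.

    Returns the matplotlib Figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(results.global_curves)
    grid = results.grid
    groups = results.groups
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharex=True)
    for ax, name in zip(axes.ravel(), names):
        mat = results.global_curves[name]
        for mask, label, color in ((groups, "IS", "tab:purple"),
                                   ((~groups), "NIS", "tab:green")):
            mean = mat[mask].mean(axis=0)
            sd = mat[mask].std(axis=0, ddof=1)
            ax.plot(grid, mean, label=label, color=color)
            ax.fill_between(grid, mean - sd, mean + sd, alpha=0.2,
                            color=color)
        ax.set_title(name)
        ax.set_xlabel("sparsity T")
    axes.ravel()[0].legend()
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_fd(fd_series, path=None):
    """FD trace with the scrubbing threshold and flagged frames."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    fd = fd_series.fd
    ax.plot(fd, lw=0.8)
    ax.axhline(fd_series.threshold, color="red", ls="--",
               label=f"threshold {fd_series.threshold} mm")
    bad = np.flatnonzero(~fd_series.keep_mask)
    ax.plot(bad, fd[bad], "rx", ms=5, label=f"{bad.size} scrubbed")
    ax.set_xlabel("volume")
    ax.set_ylabel("FD (mm)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
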