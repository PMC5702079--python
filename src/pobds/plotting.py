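"""Trajectory and model-posterior figures.

Boolean series are drawn as step functions, one panel per gene, with the
original trajectory solid black and estimates dashed red — the conventional
way filtered gene-state tracks are displayed.  Figures never mutate their
inputs and are written atomically (temp file + rename) when a path is given.
"""

from __future__ import annotations

import os
import tempfile

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mmae import MMAEResult

__all__ = ["plot_trajectory", "plot_mmae_posterior"]

_STYLES = [
    {"color": "black", "linestyle": "-"},
    {"color": "red", "linestyle": "--"},
    {"color": "tab:blue", "linestyle": ":"},
    {"color": "tab:green", "linestyle": "-."},
]


def _atomic_save(fig, path):
    path = os.fspath(path)
    ext = os.path.splitext(path)[1] or ".png"
    fd, tmp = tempfile.mkstemp(suffix=ext, dir=os.path.dirname(path) or ".")
    os.close(fd)
    try:
        fig.savefig(tmp, bbox_inches="tight", dpi=150)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def plot_trajectory(series: dict, gene_names, gene_subset=None, path=None):
    """One panel per selected gene, each named series overlaid.

    Parameters
    ----------
    series : dict mapping label -> (n, d) matrix
        E.g. ``{"original": X, "estimated": Xhat}``; Boolean matrices are
        drawn as step functions, continuous ones as lines.
    gene_names : ordered gene names matching the matrix columns.
    gene_subset : optional list of gene names to plot (default: all).
    path : optional figure file; when given the figure is saved and closed.
    """
    gene_names = list(gene_names)
    if not series:
        raise ValueError("no series to plot")
    mats = {k: np.atleast_2d(np.asarray(v)) for k, v in series.items()}
    shapes = {m.shape for m in mats.values()}
    if len(shapes) != 1:
        raise ValueError(f"all series must share one shape, got {sorted(shapes)}")
    (n, d), = shapes
    if d != len(gene_names):
        raise ValueError(f"series have {d} columns but {len(gene_names)} gene names given")
    subset = gene_names if gene_subset is None else list(gene_subset)
    if not subset:
        raise ValueError("gene_subset must be non-empty")
    for g in subset:
        if g not in gene_names:
            raise ValueError(f"unknown gene {g!r}; network genes: {', '.join(gene_names)}")

    fig, axes = plt.subplots(len(subset), 1, figsize=(8, 1.8 * len(subset)),
                             sharex=True, squeeze=False)
    t = np.arange(1, n + 1)
    for ax_row, g in zip(axes[:, 0], subset):
        j = gene_names.index(g)
        for (label, mat), style in zip(mats.items(), _STYLES):
            col = mat[:, j]
            boolean = np.all(np.isin(col, (0, 1)))
            if boolean:
                ax_row.step(t, col, where="post", label=label, **style)
                ax_row.set_ylim(-0.15, 1.15)
                ax_row.set_yticks([0, 1])
            else:
                ax_row.plot(t, col, label=label, **style)
        ax_row.set_ylabel(g)
    axes[0, 0].legend(loc="upper right", fontsize=8)
    axes[-1, 0].set_xlabel("time step")
    fig.tight_layout()
    if path is not None:
        _atomic_save(fig, path)
        plt.close(fig)
    return fig


def plot_mmae_posterior(result: MMAEResult, true_model_index=None, path=None):
    """Posterior probability of the selected (or designated) model over time,
    with the stopping threshold drawn as a horizontal rule."""
    hist = np.asarray(result.posterior_history)
    if hist.size == 0:
        raise ValueError("posterior history is empty")
    idx = true_model_index
    if idx is None:
        idx = result.selected_model if result.selected_model is not None else result.argmax_model
    t = np.arange(1, hist.shape[0] + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, hist[:, idx], marker="o", color="black",
            label=f"model {result.labels[idx]}")
    ax.axhline(result.threshold, color="red", linestyle="--",
               label=f"threshold {result.threshold:g}")
    ax.set_xlabel("time step")
    ax.set_ylabel("posterior model probability")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        _atomic_save(fig, path)
        plt.close(fig)
    return fig
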