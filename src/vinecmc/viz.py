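"""Minimal plotting helpers (tau heatmap, threshold curve)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_tau_heatmap", "plot_degree_curve"]


def plot_tau_heatmap(tau, labels=None, ax=None, title=None):
    import matplotlib.pyplot as plt

    tau = np.asarray(tau)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(tau, vmin=-1, vmax=1, cmap="RdBu_r")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(labels)), labels, fontsize=7)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="Kendall tau")
    return ax


def plot_degree_curve(curve, sd=None, n_nodes=None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ts = sorted(curve)
    ks = [curve[t] for t in ts]
    err = [sd[t] for t in ts] if sd else None
    ax.errorbar(ts, ks, yerr=err, marker="o", ms=3, capsize=2)
    if n_nodes:
        ax.axhline(2 * np.log(n_nodes), ls="--", c="gray", label="2 ln N")
        ax.legend()
    ax.set_xlabel("threshold")
    ax.set_ylabel("average node degree K")
    return ax
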