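"""Convenience renderings (volcano, heat maps). Not part of the numeric
pipeline; every figure is a plain view of a table computed elsewhere."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano", "residual_heatmap", "expression_heatmap"]


def volcano(table: pd.DataFrame, path, title: str = "") -> None:
    """Volcano plot: log2 effect (NPX difference) vs -log10 p, FDR hits colored."""
    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(np.maximum(table["p_value"].to_numpy(), 1e-300))
    rejected = table["rejected"].to_numpy()
    up = rejected & (table["effect"].to_numpy() > 0)
    down = rejected & (table["effect"].to_numpy() <= 0)
    rest = ~rejected
    ax.scatter(table.loc[rest, "effect"], logp[rest], s=12, c="0.6")
    ax.scatter(table.loc[up, "effect"], logp[up], s=16, c="firebrick", label="up")
    ax.scatter(table.loc[down, "effect"], logp[down], s=16, c="seagreen", label="down")
    ax.axhline(-np.log10(0.05), color="steelblue", lw=0.8)
    ax.set_xlabel("effect (NPX difference; log2 ratio)")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    if rejected.any():
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def residual_heatmap(values: pd.DataFrame, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8, label="residual Spearman")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def expression_heatmap(values: pd.DataFrame, path, title: str = "",
                       log: bool = True) -> None:
    arr = values.to_numpy()
    if log:
        arr = np.log2(np.maximum(arr, 1e-12))
    fig, ax = plt.subplots(figsize=(6, 5))
    lim = np.nanmax(np.abs(arr)) or 1.0
    im = ax.imshow(arr, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
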