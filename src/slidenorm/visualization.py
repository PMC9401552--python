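"""Diagnostic plots for raw-vs-normalized comparison.

All four plot functions are pure with respect to the dataset, render
headlessly, and return a :class:`FigureHandle` that can be saved to
PNG/SVG/PDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .core_data import MxDataset
from .evaluation import MissingAnalysisError

__all__ = [
    "FigureHandle",
    "plot_density",
    "plot_discordance",
    "plot_umap",
    "plot_proportions",
]

_FORMATS = ("png", "svg", "pdf")


@dataclass
class FigureHandle:
    """A rendered figure plus a save helper."""

    figure: plt.Figure

    def save(self, path) -> Path:
        path = Path(path)
        fmt = path.suffix.lstrip(".").lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported figure format {fmt!r}; use one of {_FORMATS}")
        self.figure.savefig(path, format=fmt, bbox_inches="tight")
        return path

    def close(self) -> None:
        plt.close(self.figure)


def plot_density(dataset: MxDataset, table: str = "both") -> FigureHandle:
    """Small multiples of per-slide marker densities (one panel per marker x table).

    Densities are Gaussian KDEs with Scott's-rule bandwidth; coincident
    curves across slides indicate homogeneous marker distributions.
    """
    tables = dataset.resolve_tables(table)
    markers = dataset.marker_cols
    if not len(dataset.data):
        raise ValueError("dataset is empty")
    fig, axes = plt.subplots(
        len(tables),
        len(markers),
        figsize=(3.2 * len(markers), 2.6 * len(tables)),
        squeeze=False,
    )
    for i, tab in enumerate(tables):
        df = dataset.table(tab)
        for j, marker in enumerate(markers):
            ax = axes[i][j]
            for slide, grp in df.groupby(dataset.slide_id, observed=True):
                v = grp[marker].to_numpy(dtype=float)
                if np.ptp(v) == 0:
                    ax.axvline(v[0], alpha=0.6, label=str(slide))
                    continue
                kde = gaussian_kde(v)  # Scott's rule by default
                pad = 4.0 * kde.factor * v.std()
                grid = np.linspace(v.min() - pad, v.max() + pad, 200)
                ax.plot(grid, kde(grid), alpha=0.7, label=str(slide))
            ax.set_title(f"{marker} ({tab})", fontsize=9)
            ax.set_xlabel(marker, fontsize=8)
            ax.set_ylabel("density", fontsize=8)
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right", fontsize=7, title="slide")
    fig.tight_layout()
    return FigureHandle(fig)


def plot_discordance(dataset: MxDataset) -> FigureHandle:
    """Dot plot of Otsu threshold discordance by slide, per marker and table."""
    if dataset.discordance is None:
        raise MissingAnalysisError("run_otsu_discordance has not been run")
    disc = dataset.discordance
    markers = dataset.marker_cols
    fig, axes = plt.subplots(
        1, len(markers), figsize=(3.0 * len(markers), 2.8), squeeze=False, sharey=True
    )
    colors = {"raw": "tab:gray", "normalized": "tab:blue"}
    for j, marker in enumerate(markers):
        ax = axes[0][j]
        sub = disc[disc["marker"] == marker]
        for tab, grp in sub.groupby("table"):
            ax.scatter(
                grp["discordance"],
                grp["slide_id"],
                label=tab,
                color=colors.get(tab, None),
                alpha=0.8,
            )
        ax.set_xlim(0, 1)
        ax.set_title(marker, fontsize=9)
        ax.set_xlabel("discordance", fontsize=8)
    axes[0][0].set_ylabel("slide", fontsize=8)
    axes[0][-1].legend(fontsize=7, title="table")
    fig.tight_layout()
    return FigureHandle(fig)


def plot_umap(dataset: MxDataset, color_by: str = "slide_id") -> FigureHandle:
    """Scatter of the 2-D embedding per table, colored by an attached column."""
    if dataset.umap is None:
        raise MissingAnalysisError("run_reduce_umap has not been run")
    emb = dataset.umap
    if color_by not in emb.columns:
        raise ValueError(
            f"color_by column {color_by!r} not in the embedding table "
            f"(available: {[c for c in emb.columns if c not in ('u1', 'u2')]})"
        )
    tables = list(dict.fromkeys(emb["table"]))
    fig, axes = plt.subplots(
        1, len(tables), figsize=(3.6 * len(tables), 3.2), squeeze=False
    )
    levels = list(dict.fromkeys(emb[color_by]))
    cmap = plt.get_cmap("tab10")
    for j, tab in enumerate(tables):
        ax = axes[0][j]
        sub = emb[emb["table"] == tab]
        for k, lev in enumerate(levels):
            pts = sub[sub[color_by] == lev]
            ax.scatter(pts["u1"], pts["u2"], s=4, alpha=0.6,
                       color=cmap(k % 10), label=str(lev))
        ax.set_title(tab, fontsize=9)
        ax.set_xlabel("UMAP 1", fontsize=8)
        ax.set_ylabel("UMAP 2", fontsize=8)
    axes[0][-1].legend(fontsize=7, title=color_by, markerscale=2)
    fig.tight_layout()
    return FigureHandle(fig)


def plot_proportions(dataset: MxDataset) -> FigureHandle:
    """Stacked bars of slide vs residual variance share per marker and table."""
    if dataset.var_props is None:
        raise MissingAnalysisError("run_var_proportions has not been run")
    vp = dataset.var_props
    wide = vp.pivot_table(
        index=["table", "marker"], columns="level", values="proportion"
    ).reset_index()
    labels = [f"{m}\n({t})" for t, m in zip(wide["table"], wide["marker"])]
    fig, ax = plt.subplots(figsize=(0.9 * len(wide) + 1.5, 3.2))
    x = np.arange(len(wide))
    slide_part = wide["slide"].to_numpy()
    resid_part = wide["residual"].to_numpy()
    ax.bar(x, slide_part, label="slide", color="tab:orange")
    ax.bar(x, resid_part, bottom=slide_part, label="residual", color="tab:blue")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("proportion of variance", fontsize=8)
    ax.set_ylim(0, 1.0)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return FigureHandle(fig)
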