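"""Visual analytics of a metric table: parallel coordinates across the 11
metric axes, a clustered correlation heatmap, and a PC1/PC2 scatter.

Display rescaling is strictly a plot-time transform: every plot function
takes the stored scores unchanged and never writes back.  Per-column min-max
rescaling (used by parallel coordinates) maps each column onto [0, 1] for
drawing only, so the apparent vertical spread says nothing about absolute
score differences; constant columns are pinned at 0.5 rather than divided by
zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .metrics import MetricTable
from .mining import MetricDendrogram, PCAResult

__all__ = [
    "rescale_columns",
    "parallel_coordinates",
    "correlation_heatmap",
    "pc_scatter",
]


def rescale_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each column to [0,1] for display; constant columns -> 0.5."""
    out = df.copy()
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        if hi > lo:
            out[col] = (out[col] - lo) / (hi - lo)
        else:
            out[col] = 0.5
    return out


def _group_colors(groups: Optional[pd.Series], index) -> Dict[str, str]:
    if groups is None:
        return {}
    labels = sorted(set(groups.reindex(index).dropna()))
    cmap = plt.get_cmap("tab10")
    return {lab: cmap(i % 10) for i, lab in enumerate(labels)}


def parallel_coordinates(
    m: Union[MetricTable, pd.DataFrame],
    groups: Optional[pd.Series] = None,
    path: Union[str, Path] = "parallel_coordinates.png",
) -> Path:
    """One polyline per candidate across the metric axes (per-column rescaled)."""
    df = m.scores if isinstance(m, MetricTable) else m
    if df.empty:
        raise ValueError("empty metric table")
    scaled = rescale_columns(df)
    colors = _group_colors(groups, df.index)
    fig, ax = plt.subplots(figsize=(10, 5))
    xs = np.arange(len(df.columns))
    seen = set()
    for rid, row in scaled.iterrows():
        lab = groups.get(rid) if groups is not None else None
        color = colors.get(lab, "steelblue")
        ax.plot(
            xs,
            row.to_numpy(),
            color=color,
            alpha=0.5,
            linewidth=0.8,
            label=lab if lab is not None and lab not in seen else None,
        )
        seen.add(lab)
    ax.set_xticks(xs)
    ax.set_xticklabels(df.columns)
    ax.set_ylabel("per-column rescaled score")
    ax.set_title("Metric battery, one line per candidate")
    if colors:
        ax.legend(loc="lower left", fontsize="small")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def correlation_heatmap(
    c: pd.DataFrame,
    dendro: Optional[MetricDendrogram] = None,
    path: Union[str, Path] = "correlation_heatmap.png",
) -> Path:
    """Heatmap of the metric correlation matrix, rows/cols in dendrogram leaf order."""
    order = dendro.leaf_order if dendro is not None else list(c.columns)
    cc = c.loc[order, order]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cc.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order)
    fig.colorbar(im, ax=ax, label="Spearman correlation")
    ax.set_title("Metric consistency (clustered)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def pc_scatter(
    p: PCAResult,
    groups: Optional[pd.Series] = None,
    path: Union[str, Path] = "pc_scatter.png",
) -> Path:
    """Candidates in the plane of the first two principal components."""
    scores = p.scores
    if "PC2" not in scores.columns:
        raise ValueError("need at least two principal components to scatter")
    colors = _group_colors(groups, scores.index)
    fig, ax = plt.subplots(figsize=(7, 6))
    if colors:
        for lab, col in colors.items():
            idx = [i for i in scores.index if groups.get(i) == lab]
            ax.scatter(
                scores.loc[idx, "PC1"], scores.loc[idx, "PC2"],
                s=18, color=col, label=lab, alpha=0.8,
            )
        ax.legend(fontsize="small")
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=18, color="steelblue", alpha=0.8)
    var = p.eigenvalues / p.eigenvalues.sum() * 100.0
    ax.set_xlabel(f"PC1 ({var[0]:.1f}% of rank variance)")
    ax.set_ylabel(f"PC2 ({var[1]:.1f}% of rank variance)")
    ax.set_title("Rank-PCA candidate map")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
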