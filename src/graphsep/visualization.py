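"""The four standard figures: graph plot, neighbor-probability heatmap,
class-colored community histogram, and log-log degree distribution.

Layout coordinates come from the manifold embedding when the nodes carry
one (creating the bridge between dimensionality reduction and network
drawing); otherwise a seeded Fruchterman-Reingold force layout is used.
All files are written as PNG at 150 dpi; with ``overwrite=False`` an
existing file is refused rather than clobbered.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .graph_analysis import (
    LABEL_KEY,
    CommunityPartition,
    NeighborProbabilityMatrix,
)

__all__ = [
    "compute_layout",
    "plot_graph",
    "plot_heatmap",
    "plot_communities",
    "plot_degree_distribution",
]

DPI = 150
# binary targets: class 0 red, class 1 blue; larger label sets fall back to
# a categorical palette keyed by sorted label order
_TWO_CLASS_COLORS = ["tab:red", "tab:blue"]


def _check_path(path, overwrite: bool) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; set overwrite=true to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def compute_layout(g: nx.Graph, seed: int = 42) -> dict:
    """2-D coordinates per node: embedding passthrough or force-directed.

    Nodes carrying ``manifold_0`` (and ``manifold_1``) attributes are placed
    at those coordinates verbatim (a 1-D embedding is padded with zeros,
    with a warning); otherwise the seeded spring layout is used, so the
    result is deterministic for a fixed seed.
    """
    nodes = list(g.nodes)
    if nodes and all("manifold_0" in g.nodes[v] for v in nodes):
        if all("manifold_1" in g.nodes[v] for v in nodes):
            return {
                v: (float(g.nodes[v]["manifold_0"]), float(g.nodes[v]["manifold_1"]))
                for v in nodes
            }
        warnings.warn(
            "1-D manifold embedding: second layout coordinate padded with 0",
            UserWarning,
        )
        return {v: (float(g.nodes[v]["manifold_0"]), 0.0) for v in nodes}
    return {
        v: (float(x), float(y))
        for v, (x, y) in nx.spring_layout(g, seed=int(seed)).items()
    }


def _label_colors(labels: list) -> dict:
    classes = sorted(set(labels), key=str)
    if len(classes) <= 2:
        return dict(zip(classes, _TWO_CLASS_COLORS))
    cmap = plt.get_cmap("tab10" if len(classes) <= 10 else "tab20")
    return {c: cmap(i % cmap.N) for i, c in enumerate(classes)}


def plot_graph(
    g: nx.Graph,
    coords: Optional[dict] = None,
    path="graph.png",
    overwrite: bool = False,
    seed: int = 42,
    label_attr: str = LABEL_KEY,
) -> Path:
    """Draw the graph with class-colored nodes; isolated nodes stay visible
    (they flag potential outliers)."""
    path = _check_path(path, overwrite)
    if coords is None:
        coords = compute_layout(g, seed=seed)
    labeled = g.number_of_nodes() > 0 and all(
        label_attr in g.nodes[v] for v in g.nodes
    )
    fig, ax = plt.subplots(figsize=(7, 6))
    if labeled:
        labels = [g.nodes[v][label_attr] for v in g.nodes]
        palette = _label_colors(labels)
        colors = [palette[l] for l in labels]
    else:
        colors = "tab:gray"
    nx.draw_networkx_edges(g, coords, ax=ax, alpha=0.25, width=0.6)
    nx.draw_networkx_nodes(g, coords, ax=ax, node_color=colors, node_size=22)
    if labeled:
        handles = [
            plt.Line2D(
                [], [], marker="o", linestyle="", color=c, label=str(l)
            )
            for l, c in _label_colors(labels).items()
        ]
        ax.legend(handles=handles, title="class", loc="best", fontsize=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=DPI)
    plt.close(fig)
    return path


def plot_heatmap(
    P: NeighborProbabilityMatrix, path="neigh_prob_heatmap.png", overwrite=False
) -> Path:
    """Annotated c x c heatmap of neighbor probabilities on a fixed [0, 1]
    scale; undefined rows (classes without edges) are blanked and noted."""
    path = _check_path(path, overwrite)
    c = len(P.labels)
    fig, ax = plt.subplots(figsize=(1.2 * c + 3, 1.2 * c + 2.5))
    shown = np.where(np.isnan(P.probabilities), 0.0, P.probabilities)
    im = ax.imshow(shown, vmin=0.0, vmax=1.0, cmap="viridis")
    for i in range(c):
        for j in range(c):
            if P.undefined[i]:
                text = "n/a"
            else:
                text = f"{P.probabilities[i, j]:.2f}"
            ax.text(
                j,
                i,
                text,
                ha="center",
                va="center",
                color="white" if shown[i, j] < 0.6 else "black",
                fontsize=10,
            )
    names = [str(l) for l in P.labels]
    ax.set_xticks(range(c), names)
    ax.set_yticks(range(c), names)
    ax.set_xlabel("neighbor class")
    ax.set_ylabel("source class")
    if P.undefined.any():
        ax.set_title("rows marked n/a: class has no incident edges", fontsize=9)
    fig.colorbar(im, ax=ax, label="P(neighbor class | source class)")
    fig.tight_layout()
    fig.savefig(path, dpi=DPI)
    plt.close(fig)
    return path


def plot_communities(
    partition: CommunityPartition,
    path="communities.png",
    overwrite: bool = False,
) -> Path:
    """Bar chart of community sizes (decreasing); when the partition knows
    the class composition each bar is a stacked bar of class counts."""
    path = _check_path(path, overwrite)
    sizes = partition.sizes()
    ids = list(range(len(sizes)))
    fig, ax = plt.subplots(figsize=(max(5, 0.4 * len(sizes) + 3), 4.5))
    if partition.composition is not None:
        classes = sorted(
            {l for counts in partition.composition for l in counts}, key=str
        )
        palette = _label_colors(classes)
        bottom = np.zeros(len(sizes))
        for cls in classes:
            heights = np.array(
                [counts.get(cls, 0) for counts in partition.composition], float
            )
            ax.bar(
                ids, heights, bottom=bottom, color=palette[cls], label=str(cls)
            )
            bottom += heights
        ax.legend(title="class", fontsize=8)
    else:
        ax.bar(ids, sizes, color="tab:gray")
    ax.set_xlabel("community ID")
    ax.set_ylabel("cardinality")
    fig.tight_layout()
    fig.savefig(path, dpi=DPI)
    plt.close(fig)
    return path


def plot_degree_distribution(
    hist: dict, path="degree.png", overwrite: bool = False
) -> Path:
    """Double-log scatter of degree vs node count for degrees >= 1.

    Degree-0 nodes cannot sit on a log axis; their count is reported in a
    caption instead (they are the isolated-node/outlier signal)."""
    path = _check_path(path, overwrite)
    isolated = hist.get(0, 0)
    degrees = sorted(d for d in hist if d >= 1)
    counts = [hist[d] for d in degrees]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if degrees:
        ax.scatter(degrees, counts, s=28, color="tab:blue")
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("degree")
    ax.set_ylabel("node count")
    if isolated:
        ax.set_title(f"{isolated} isolated node(s) at degree 0", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=DPI)
    plt.close(fig)
    return path
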