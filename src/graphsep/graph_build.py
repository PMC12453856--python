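"""Similarity-graph construction over table rows.

Three rules turn a numeric feature matrix into an undirected attributed
graph: k-nearest neighbors under Euclidean distance (union-symmetrized),
a strict Euclidean distance threshold, and a strict cosine-similarity
threshold.  Nodes are row indices and carry the full feature vector, the
target label and any manifold-layout coordinates as attributes; graphs
interchange via GraphML.
"""

from __future__ import annotations

import warnings
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils import check_array

from .config import Config, validate_config
from .preprocessing import PreprocessedTable

__all__ = [
    "knn_graph",
    "distance_graph",
    "similarity_graph",
    "build_graph",
    "write_graphml",
    "read_graphml",
    "KNNGraphBuilder",
    "DistanceGraphBuilder",
    "SimilarityGraphBuilder",
    "GraphBuildError",
]


class GraphBuildError(ValueError):
    """Invalid graph-construction parameters."""


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, dtype=float)))


def knn_graph(X, k: int, mutual: bool = False) -> nx.Graph:
    """Undirected k-nearest-neighbor graph under Euclidean distance.

    Each row points at its ``k`` nearest other rows (distance ties broken by
    the smaller row index); the directed relation is symmetrized by union,
    so every node ends up with degree >= k.  ``mutual=True`` switches to
    intersection symmetrization (edge only if both point at each other),
    provided for comparison; it can leave nodes isolated.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = int(k)
    if k < 1:
        raise GraphBuildError("k must be >= 1")
    if k >= n:
        raise GraphBuildError(f"k={k} must be smaller than the number of rows n={n}")
    D = _distance_matrix(X)
    np.fill_diagonal(D, np.inf)
    # stable argsort == tie-break by ascending row index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if mutual:
        out = [set(row) for row in order]
        for u in range(n):
            for v in order[u]:
                if u < v and u in out[v]:
                    g.add_edge(u, int(v))
    else:
        for u in range(n):
            for v in order[u]:
                g.add_edge(u, int(v))
    return g


def distance_graph(X, threshold: float) -> nx.Graph:
    """Edge between rows whose Euclidean distance is strictly below ``threshold``.

    Rows farther than the threshold from everything stay as isolated nodes
    (they are the outlier signal downstream).
    """
    if threshold is None or float(threshold) <= 0:
        raise GraphBuildError("distance_threshold must be > 0")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = _distance_matrix(X)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.where(np.triu(D < float(threshold), k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def similarity_graph(X, threshold: float) -> nx.Graph:
    """Edge between rows whose cosine similarity is strictly above ``threshold``.

    Zero-norm rows have undefined direction; their similarity to everything
    is taken as 0 (with a warning).
    """
    t = float(threshold)
    if not (-1.0 <= t <= 1.0):
        raise GraphBuildError("similarity_threshold must lie in [-1, 1]")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-norm row(s): cosine similarity taken as 0",
            UserWarning,
        )
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.where(np.triu(S > t, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


class _GraphBuilderBase(BaseEstimator):
    """Estimator interface: ``fit(X)`` builds ``graph_`` over the rows of X."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.graph_ = self._build(X)
        self.n_features_in_ = X.shape[1]
        if y is not None:
            labels = np.asarray(y)
            for node in self.graph_.nodes:
                self.graph_.nodes[node]["label"] = _scalar(labels[node])
        return self

    def fit_transform(self, X, y=None) -> nx.Graph:
        return self.fit(X, y).graph_


class KNNGraphBuilder(_GraphBuilderBase):
    """k-nearest-neighbor graph builder (Euclidean, union-symmetrized)."""

    def __init__(self, k: int = 5, mutual: bool = False):
        self.k = k
        self.mutual = mutual

    def _build(self, X):
        return knn_graph(X, self.k, mutual=self.mutual)


class DistanceGraphBuilder(_GraphBuilderBase):
    """Radius graph builder: edges strictly below a Euclidean distance."""

    def __init__(self, threshold: float = 1.0):
        self.threshold = threshold

    def _build(self, X):
        return distance_graph(X, self.threshold)


class SimilarityGraphBuilder(_GraphBuilderBase):
    """Cosine-similarity graph builder: edges strictly above a threshold."""

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def _build(self, X):
        return similarity_graph(X, self.threshold)


def _scalar(value):
    """Coerce an attribute value to a GraphML-serializable Python scalar."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        return float(value)
    return str(value)


def build_graph(pt: PreprocessedTable, config: Config) -> nx.Graph:
    """Dispatch on ``config.method`` and attach node attributes.

    Every node carries its feature vector (one attribute per feature
    column), the primary target label under ``label`` (when a target is
    configured), and manifold coordinates under ``manifold_0..`` (when an
    embedding was computed).  Distances always use the preprocessed feature
    space, never the embedding, which is reserved for layout.
    """
    config = validate_config(config)
    X = pt.X.to_numpy(dtype=float)
    if config.method == "knn":
        g = knn_graph(X, config.k)
    elif config.method == "distance":
        g = distance_graph(X, config.distance_threshold)
    else:
        g = similarity_graph(X, config.similarity_threshold)

    mapping = {i: int(pt.ids[i]) for i in range(len(pt.ids))}
    g = nx.relabel_nodes(g, mapping)

    target = pt.primary_target
    for i, node in mapping.items():
        attrs = g.nodes[node]
        for name, value in zip(pt.feature_names, X[i]):
            attrs[str(name)] = float(value)
        if target is not None:
            attrs["label"] = _scalar(target.iloc[i])
        if pt.embedding is not None:
            for j in range(pt.embedding.shape[1]):
                attrs[f"manifold_{j}"] = float(pt.embedding[i, j])

    if config.graph_filename:
        from pathlib import Path

        out = Path(config.output_directory) / config.graph_filename
        out.parent.mkdir(parents=True, exist_ok=True)
        if out.exists() and not config.overwrite:
            raise FileExistsError(f"{out} exists; set overwrite=true to replace it")
        write_graphml(g, out)
    return g


def write_graphml(g: nx.Graph, path) -> None:
    """Serialize an attributed graph to GraphML with typed attribute keys."""
    clean = nx.Graph()
    clean.add_nodes_from(
        (node, {k: _scalar(v) for k, v in data.items()})
        for node, data in g.nodes(data=True)
    )
    clean.add_edges_from(g.edges())
    nx.write_graphml(clean, str(path))


def read_graphml(path) -> nx.Graph:
    """Read a GraphML file into an undirected attributed graph.

    Directed input is accepted and collapsed to undirected with a warning;
    node ids that all parse as integers are restored to integers so that a
    write/read round-trip is the identity.
    """
    g = nx.read_graphml(str(path))
    if g.is_directed():
        warnings.warn("directed GraphML input converted to undirected", UserWarning)
        g = nx.Graph(g.to_undirected())
    if g.is_multigraph():
        g = nx.Graph(g)
    try:
        mapping = {node: int(node) for node in g.nodes}
    except (TypeError, ValueError):
        return g
    return nx.relabel_nodes(g, mapping)
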