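"""Topology and class-separation statistics for attributed graphs.

Implements the neighbor-probability matrix, homophily score with a
permutation null (z-score and empirical p), a chi-square independence test
on the neighbor contingency table, Girvan-Newman community detection with
max-modularity level selection, and the standard topology metrics (density,
clustering, components, assortativity, degree distribution).

Counting convention: every undirected edge contributes its two ordered
endpoints, so the c x c contingency table C satisfies sum(C) = 2|E| and is
symmetric.  The neighbor-probability matrix is the row-normalization of C,
and the chi-square test runs on C itself, keeping the two views consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import islice
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy import stats

from .config import Config

__all__ = [
    "neighbor_probability",
    "homophily",
    "homophily_permutation_test",
    "neighbor_chi_square",
    "detect_communities",
    "modularity",
    "basic_metrics",
    "assortativity",
    "degree_distribution",
    "build_report",
    "NeighborProbabilityMatrix",
    "CommunityPartition",
    "PermutationResult",
    "SeparationReport",
    "GraphAnalysisError",
]

logger = logging.getLogger("graphsep")

LABEL_KEY = "label"


class GraphAnalysisError(ValueError):
    """The requested statistic is undefined for this graph."""


def _node_labels(g: nx.Graph, label_attr: str = LABEL_KEY):
    """Nodes in deterministic sorted order with their labels.

    Raises when any node lacks the label attribute.
    """
    try:
        nodes = sorted(g.nodes)
    except TypeError:
        nodes = sorted(g.nodes, key=str)
    missing = [v for v in nodes if label_attr not in g.nodes[v]]
    if missing:
        raise GraphAnalysisError(
            f"{len(missing)} node(s) lack the {label_attr!r} attribute"
        )
    return nodes, [g.nodes[v][label_attr] for v in nodes]


@dataclass
class NeighborProbabilityMatrix:
    """Row-stochastic matrix P[i, j] = P(neighbor has class j | node has class i)."""

    labels: list
    probabilities: np.ndarray
    counts: np.ndarray
    undefined: np.ndarray  # boolean mask of classes with no incident edges

    def to_text(self) -> str:
        """Aligned text table: header of class labels, one row per source class."""
        names = [str(l) for l in self.labels]
        width = max(8, max((len(n) for n in names), default=8) + 2)
        head = " " * width + "".join(f"{n:>{width}}" for n in names)
        lines = [head]
        for i, name in enumerate(names):
            if self.undefined[i]:
                cells = "".join(f"{'n/a':>{width}}" for _ in names)
            else:
                cells = "".join(
                    f"{self.probabilities[i, j]:>{width}.4f}"
                    for j in range(len(names))
                )
            lines.append(f"{name:<{width}}" + cells)
        return "\n".join(lines) + "\n"


def _endpoint_counts(g: nx.Graph, label_attr: str = LABEL_KEY):
    nodes, labels = _node_labels(g, label_attr)
    classes = sorted(set(labels), key=str)
    index = {c: i for i, c in enumerate(classes)}
    node_class = dict(zip(nodes, labels))
    C = np.zeros((len(classes), len(classes)), dtype=float)
    for u, v in g.edges:
        i, j = index[node_class[u]], index[node_class[v]]
        C[i, j] += 1
        C[j, i] += 1
    return classes, C


def neighbor_probability(
    g: nx.Graph, label_attr: str = LABEL_KEY
) -> NeighborProbabilityMatrix:
    """Probability that a neighbor of a class-i node belongs to class j.

    Diagonal entries near 1 mean nodes connect almost exclusively within
    their own class (strong separation); a class with no incident edges has
    an undefined row, flagged and warned about.
    """
    classes, C = _endpoint_counts(g, label_attr)
    totals = C.sum(axis=1)
    undefined = totals == 0
    if undefined.any():
        bad = [str(c) for c, u in zip(classes, undefined) if u]
        warnings.warn(
            f"class(es) with no incident edges have undefined rows: {bad}",
            UserWarning,
        )
    P = np.full_like(C, np.nan)
    ok = ~undefined
    P[ok] = C[ok] / totals[ok, None]
    return NeighborProbabilityMatrix(
        labels=classes, probabilities=P, counts=C, undefined=undefined
    )


def homophily(g: nx.Graph, label_attr: str = LABEL_KEY) -> float:
    """Fraction of edges whose endpoints share a class label."""
    m = g.number_of_edges()
    if m == 0:
        raise GraphAnalysisError("homophily undefined on empty edge set")
    _node_labels(g, label_attr)  # validates every node is labeled
    same = sum(
        1 for u, v in g.edges if g.nodes[u][label_attr] == g.nodes[v][label_attr]
    )
    return same / m


@dataclass
class PermutationResult:
    """Permutation-null summary for the homophily score."""

    observed: float
    z: float  # NaN when the null has zero spread (e.g. single-class graph)
    p_empirical: float
    null_mean: float
    null_sd: float
    n_permutations: int
    seed: int

    @property
    def z_defined(self) -> bool:
        return np.isfinite(self.z)


def homophily_permutation_test(
    g: nx.Graph,
    n_perm: int = 1000,
    seed: int = 42,
    label_attr: str = LABEL_KEY,
) -> PermutationResult:
    """Permutation test of the homophily score.

    Labels are shuffled across nodes (multiset preserved, topology fixed)
    ``n_perm`` times.  Returns z = (obs - mean) / sd over the null draws and
    the one-sided smoothed empirical p, (1 + #{null >= obs}) / (n_perm + 1).
    A single-class graph has a degenerate null; z is NaN there while the
    empirical p is still reported.
    """
    if g.number_of_edges() == 0:
        raise GraphAnalysisError("homophily undefined on empty edge set")
    if int(n_perm) < 1:
        raise GraphAnalysisError("n_perm must be >= 1")
    nodes, labels = _node_labels(g, label_attr)
    labels = np.asarray([str(l) for l in labels], dtype=object)
    pos = {v: i for i, v in enumerate(nodes)}
    ui = np.fromiter((pos[u] for u, v in g.edges), dtype=int)
    vi = np.fromiter((pos[v] for u, v in g.edges), dtype=int)
    observed = float((labels[ui] == labels[vi]).mean())

    rng = np.random.default_rng(int(seed))
    null = np.empty(int(n_perm))
    for t in range(int(n_perm)):
        perm = labels[rng.permutation(len(labels))]
        null[t] = (perm[ui] == perm[vi]).mean()
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            "degenerate permutation null (zero spread); z-score undefined",
            UserWarning,
        )
        z = float("nan")
    else:
        z = (observed - mean) / sd
    p_emp = (1 + int((null >= observed - 1e-15).sum())) / (int(n_perm) + 1)
    return PermutationResult(
        observed=observed,
        z=z,
        p_empirical=p_emp,
        null_mean=mean,
        null_sd=sd,
        n_permutations=int(n_perm),
        seed=int(seed),
    )


def neighbor_chi_square(g: nx.Graph, label_attr: str = LABEL_KEY):
    """Pearson chi-square of independence on the ordered-endpoint table.

    Classes without incident edges are dropped (warned) before testing;
    with c remaining classes the test has (c-1)^2 degrees of freedom.
    Returns ``(statistic, p_value)``.
    """
    classes, C = _endpoint_counts(g, label_attr)
    keep = C.sum(axis=1) > 0
    if keep.sum() < C.shape[0]:
        dropped = [str(c) for c, k in zip(classes, keep) if not k]
        warnings.warn(f"dropping edgeless class(es) from chi-square: {dropped}")
    C = C[np.ix_(keep, keep)]
    if C.shape[0] < 2:
        raise GraphAnalysisError(
            "chi-square needs at least two classes with incident edges"
        )
    statistic, p, dof, _ = stats.chi2_contingency(C, correction=False)
    assert dof == (C.shape[0] - 1) ** 2
    return float(statistic), float(p)


@dataclass
class CommunityPartition:
    """Disjoint exhaustive node communities, ids 0.. ordered by decreasing size."""

    node_to_community: dict
    communities: list  # list of sets, index == community id
    modularity: float
    composition: Optional[list] = None  # per-community {label: count}

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def sizes(self) -> list:
        return [len(c) for c in self.communities]


def _most_valuable_edge(g: nx.Graph):
    """Highest-betweenness edge; ties broken by lexicographic edge id."""
    betweenness = nx.edge_betweenness_centrality(g)
    best_value = max(betweenness.values())
    candidates = [
        e for e, b in betweenness.items() if b >= best_value - 1e-12
    ]
    return min(candidates, key=lambda e: tuple(sorted((str(e[0]), str(e[1])))))


def _order_communities(communities):
    return sorted(
        (set(c) for c in communities),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )


def detect_communities(
    g: nx.Graph, max_splits: int = 100, label_attr: str = LABEL_KEY
) -> CommunityPartition:
    """Girvan-Newman divisive community detection, max-modularity selection.

    Starting from the connected-components partition, the highest-edge-
    betweenness edge is removed repeatedly; each time the component count
    grows the partition is recorded, up to ``max_splits`` recorded splits.
    The recorded partition with maximal modularity wins (ties -> fewer
    communities; the initial components partition is always a candidate).
    """
    if g.number_of_nodes() == 0:
        raise GraphAnalysisError("cannot detect communities on an empty graph")
    if g.number_of_edges() == 0:
        raise GraphAnalysisError("community detection requires at least one edge")
    candidates = [list(nx.connected_components(g))]
    generator = nx.community.girvan_newman(
        g, most_valuable_edge=_most_valuable_edge
    )
    for partition in islice(generator, int(max_splits)):
        candidates.append([set(c) for c in partition])

    best, best_q = None, -np.inf
    for partition in candidates:
        q = nx.community.modularity(g, partition)
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12 and best is not None and len(partition) < len(best)
        ):
            best, best_q = partition, q

    communities = _order_communities(best)
    node_to_community = {
        v: cid for cid, members in enumerate(communities) for v in members
    }
    composition = None
    if all(label_attr in g.nodes[v] for v in g.nodes):
        composition = []
        for members in communities:
            counts: dict = {}
            for v in members:
                lbl = g.nodes[v][label_attr]
                counts[lbl] = counts.get(lbl, 0) + 1
            composition.append(counts)
    return CommunityPartition(
        node_to_community=node_to_community,
        communities=communities,
        modularity=float(best_q),
        composition=composition,
    )


def modularity(g: nx.Graph, partition) -> float:
    """Newman modularity Q of a partition (list of sets or CommunityPartition)."""
    if g.number_of_edges() == 0:
        raise GraphAnalysisError("modularity undefined on empty edge set")
    communities = (
        partition.communities
        if isinstance(partition, CommunityPartition)
        else list(partition)
    )
    return float(nx.community.modularity(g, communities))


def basic_metrics(g: nx.Graph):
    """(density, average clustering, component count, largest-component %).

    Density is 2|E|/(|V|(|V|-1)); nodes of degree < 2 contribute clustering
    0 to the average; the largest-component share is a percentage rounded
    to one decimal.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise GraphAnalysisError("basic metrics need at least two nodes")
    density = nx.density(g)
    avg_clustering = nx.average_clustering(g)
    components = list(nx.connected_components(g))
    largest_pct = round(100.0 * max(len(c) for c in components) / n, 1)
    return float(density), float(avg_clustering), len(components), largest_pct


def assortativity(g: nx.Graph, label_attr: str = LABEL_KEY):
    """(attribute assortativity on the target label, degree assortativity).

    Either coefficient is NaN (with a warning) when undefined: a single
    class for the former, uniform degrees for the latter.
    """
    _, labels = _node_labels(g, label_attr)
    if len(set(labels)) < 2:
        warnings.warn("attribute assortativity undefined for a single class")
        attribute_r = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            attribute_r = float(
                nx.attribute_assortativity_coefficient(g, label_attr)
            )
    degrees = {d for _, d in g.degree()}
    if len(degrees) < 2 or g.number_of_edges() == 0:
        warnings.warn("degree assortativity undefined (uniform degrees)")
        degree_r = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            degree_r = float(nx.degree_pearson_correlation_coefficient(g))
    return attribute_r, degree_r


def degree_distribution(g: nx.Graph) -> dict:
    """Exact histogram degree -> node count (isolated nodes at degree 0)."""
    hist: dict = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


@dataclass
class SeparationReport:
    """All topology and class-separation metrics for one graph."""

    density: float
    avg_clustering: float
    connected_components: int
    largest_component_pct: float
    attribute_assortativity: Optional[float] = None
    degree_assortativity: Optional[float] = None
    community_count: Optional[int] = None
    modularity_score: Optional[float] = None
    homophily_score: Optional[float] = None
    chi2_statistic: Optional[float] = None
    chi2_p_value: Optional[float] = None
    homophily_z: Optional[float] = None
    permutation_p: Optional[float] = None
    n_permutations: Optional[int] = None
    random_seed: Optional[int] = None
    neighbor_probabilities: Optional[NeighborProbabilityMatrix] = None
    partition: Optional[CommunityPartition] = None

    def to_text(self) -> str:
        def fmt(x):
            if x is None:
                return "n/a"
            if isinstance(x, float):
                return "nan" if not np.isfinite(x) else f"{x:.4g}"
            return str(x)

        rows = [
            ("Graph density", self.density),
            ("Average clustering coefficient", self.avg_clustering),
            ("Connected components", self.connected_components),
            ("Largest component size (%)", f"{self.largest_component_pct:.1f}"),
            ("Assortativity coefficient", self.attribute_assortativity),
            ("Community count", self.community_count),
            ("Modularity score", self.modularity_score),
            ("Homophily score", self.homophily_score),
            ("Chi-square p-value", self.chi2_p_value),
            ("Homophily Z-score", self.homophily_z),
            ("Degree assortativity", self.degree_assortativity),
            ("Chi-square statistic", self.chi2_statistic),
            ("Permutation p-value", self.permutation_p),
        ]
        return "\n".join(f"{name}\t{fmt(value)}" for name, value in rows) + "\n"


def build_report(
    g: nx.Graph,
    config: Optional[Config] = None,
    max_splits: int = 100,
    label_attr: str = LABEL_KEY,
) -> SeparationReport:
    """Assemble every metric into a :class:`SeparationReport`.

    Separation statistics require node labels; on an unlabeled graph only
    the topology metrics are filled and a notice is logged.  When a config
    is given, the neighbor probabilities go to ``neigh_prob_path`` and the
    metric lines to ``network_metrics_filename`` (or the console log).
    """
    if g.number_of_edges() == 0:
        raise GraphAnalysisError(
            "graph has no edges; undefined metrics: homophily, neighbor "
            "probabilities, chi-square, permutation z, communities, modularity"
        )
    density, avg_clustering, n_components, largest_pct = basic_metrics(g)
    report = SeparationReport(
        density=density,
        avg_clustering=avg_clustering,
        connected_components=n_components,
        largest_component_pct=largest_pct,
    )

    has_labels = all(label_attr in g.nodes[v] for v in g.nodes)
    partition = detect_communities(g, max_splits=max_splits, label_attr=label_attr)
    report.partition = partition
    report.community_count = partition.n_communities
    report.modularity_score = partition.modularity

    if has_labels:
        n_perm = config.n_permutations if config is not None else 1000
        seed = config.random_seed if config is not None else 42
        report.neighbor_probabilities = neighbor_probability(g, label_attr)
        report.homophily_score = homophily(g, label_attr)
        attr_r, deg_r = assortativity(g, label_attr)
        report.attribute_assortativity = attr_r
        report.degree_assortativity = deg_r
        try:
            chi2, p = neighbor_chi_square(g, label_attr)
            report.chi2_statistic, report.chi2_p_value = chi2, p
        except GraphAnalysisError as exc:
            logger.warning("chi-square skipped: %s", exc)
        perm = homophily_permutation_test(g, n_perm, seed, label_attr)
        report.homophily_z = perm.z
        report.permutation_p = perm.p_empirical
        report.n_permutations = perm.n_permutations
        report.random_seed = perm.seed
    else:
        logger.info("no node labels: separation metrics skipped")
        degrees = {d for _, d in g.degree()}
        if len(degrees) >= 2:
            report.degree_assortativity = float(
                nx.degree_pearson_correlation_coefficient(g)
            )

    if config is not None:
        outdir = Path(config.output_directory)
        outdir.mkdir(parents=True, exist_ok=True)
        if has_labels and config.neigh_prob_path:
            path = outdir / config.neigh_prob_path
            if path.exists() and not config.overwrite:
                raise FileExistsError(
                    f"{path} exists; set overwrite=true to replace it"
                )
            path.write_text(report.neighbor_probabilities.to_text())
        if config.network_metrics_filename:
            path = outdir / config.network_metrics_filename
            if path.exists() and not config.overwrite:
                raise FileExistsError(
                    f"{path} exists; set overwrite=true to replace it"
                )
            path.write_text(report.to_text())
        else:
            logger.info("network metrics:\n%s", report.to_text())
    return report
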