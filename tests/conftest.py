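"""Shared fixtures: small labeled graphs and synthetic-table helpers."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from graphsep import BlobSpec, Config, config_from_dict, generate_table


def labeled_graph(edges, labels):
    g = nx.Graph(edges)
    for node, label in labels.items():
        g.add_node(node)
        g.nodes[node]["label"] = label
    return g


@pytest.fixture
def two_triangles():
    """Two disjoint triangles, one class each (perfect separation)."""
    return labeled_graph(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)],
        {v: (0 if v < 3 else 1) for v in range(6)},
    )


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single bridge edge."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture
def cross_bipartite():
    """Complete bipartite K3,3 with classes on opposite sides (anti-separation)."""
    g = nx.complete_bipartite_graph(3, 3)
    for v in g.nodes:
        g.nodes[v]["label"] = 0 if v < 3 else 1
    return g


@pytest.fixture
def blob_config():
    """Default pipeline config for synthetic blob tables."""

    def make(**overrides):
        raw = {
            "input_dataframe": "in-memory.csv",
            "target_columns": ["target"],
            "ignore_columns": ["id"],
        }
        raw.update(overrides)
        return config_from_dict(raw)

    return make


@pytest.fixture
def blob_table():
    def make(**kwargs):
        return generate_table(BlobSpec(**kwargs))

    return make


def random_labeled_graph(rng, n=None, p=None, n_classes=2):
    """Erdos-Renyi graph with at least one edge and random node labels."""
    n = n if n is not None else int(rng.integers(5, 40))
    p = p if p is not None else float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    while g.number_of_edges() == 0:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31 - 1)))
    for v in g.nodes:
        g.nodes[v]["label"] = int(rng.integers(0, n_classes))
    return g
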