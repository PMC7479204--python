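"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: projection
by pairwise neighbour-set intersection, modularity by the explicit
double-sum over node pairs, and the optimum partition by exhaustive
enumeration of all set partitions.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from tcmnet import SyntheticConfig, generate_dataset


# -- oracles -----------------------------------------------------------------

def brute_force_projection(edges, side_nodes):
    """Shared-neighbour projection by explicit pairwise set intersection.

    ``edges`` are (a, b) pairs; ``side_nodes`` the ids of the side being
    projected (position 0 of each pair when projecting side A).  Returns
    {frozenset({u, v}): weight}.
    """
    nbrs = {u: set() for u in side_nodes}
    for a, b in edges:
        if a in nbrs:
            nbrs[a].add(b)
    out = {}
    for u, v in itertools.combinations(sorted(side_nodes), 2):
        shared = len(nbrs[u] & nbrs[v])
        if shared:
            out[frozenset({u, v})] = shared
    return out


def direct_modularity(g: nx.Graph, assignment, weighted=True) -> float:
    """Q via the explicit (1/2W) sum over ordered node pairs."""
    nodes = list(g.nodes)
    n = len(nodes)
    A = np.zeros((n, n))
    idx = {u: i for i, u in enumerate(nodes)}
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1) if weighted else 1
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    k = A.sum(axis=1)
    two_w = A.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += A[i, j] - k[i] * k[j] / two_w
    return q / two_w


def all_set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_modularity(g: nx.Graph, weighted=True) -> float:
    """Maximum Q over every partition of the node set (n <= 8 sensible)."""
    best = -np.inf
    for blocks in all_set_partitions(g.nodes):
        assignment = {u: i for i, block in enumerate(blocks) for u in block}
        best = max(best, direct_modularity(g, assignment, weighted))
    return best


# -- fixtures ----------------------------------------------------------------

@pytest.fixture(scope="session")
def default_dataset():
    """Default planted-block dataset (3 blocks, 5% leakage, 10% noise)."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for offset in (0, 4):
        for u, v in itertools.combinations(range(offset, offset + 4), 2):
            g.add_edge(f"n{u}", f"n{v}", weight=1)
    g.add_edge("n0", "n4", weight=1)
    return g


@pytest.fixture
def two_triangles():
    """Two disjoint triangles (weight 1)."""
    g = nx.Graph()
    for offset in (0, 3):
        for u, v in itertools.combinations(range(offset, offset + 3), 2):
            g.add_edge(f"t{u}", f"t{v}", weight=1)
    return g


def random_bipartite_edges(rng, n_a=10, n_b=10, n_edges=100):
    """Random deduplicated (a, b) edge pairs over H#/I# id spaces."""
    edges = set()
    for _ in range(n_edges):
        edges.add((f"H{rng.integers(n_a)}", f"I{rng.integers(n_b)}"))
    return sorted(edges)
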