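"""Bipartite herb-ingredient graph: loading, giant component, projections.

The herb-ingredient relation is held as a two-column incidence table and
turned into a bipartite graph whose two node sets are tracked structurally
(side tags), so the same identifier string may legally occur on both sides.
Projection onto either side yields a weighted similarity network: the NSN
(natural-product similarity network, herb side) or the ISN (ingredient
similarity network), where an edge means at least one shared opposite-side
neighbour and the weight counts the shared neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import EmptyInputError, NoEdgesError, ParseError
from .estimators import BipartiteProjection

logger = logging.getLogger(__name__)

SIDE_ALIASES = {
    "A": "A", "a": "A", "herb": "A", "herbs": "A", "natural_product": "A",
    "B": "B", "b": "B", "ingredient": "B", "ingredients": "B",
}


@dataclass
class IncidenceTable:
    """Deduplicated (herb_id, ingredient_id) edge list."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        seen = set()
        unique = []
        for r in self.rows:
            if r not in seen:
                seen.add(r)
                unique.append(r)
        self.rows = unique

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def herbs(self) -> list[str]:
        return sorted({h for h, _ in self.rows})

    @property
    def ingredients(self) -> list[str]:
        return sorted({i for _, i in self.rows})

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"herb_id{delimiter}ingredient_id\n")
            for h, i in sorted(self.rows):
                fh.write(f"{h}{delimiter}{i}\n")


@dataclass
class BipartiteGraph:
    """Bipartite graph with structurally tagged sides.

    Internally nodes are ``("A", id)`` / ``("B", id)`` tuples in a
    networkx Graph, keeping the two namespaces disjoint by construction.
    """

    graph: nx.Graph = field(repr=False)

    @property
    def side_a(self) -> set[str]:
        return {i for s, i in self.graph.nodes if s == "A"}

    @property
    def side_b(self) -> set[str]:
        return {i for s, i in self.graph.nodes if s == "B"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges:
            a, b = (u, v) if u[0] == "A" else (v, u)
            out.add((a[1], b[1]))
        return out


def load_incidence(path: str | Path, delimiter: str = "\t") -> IncidenceTable:
    """Read a two-column incidence TSV into an :class:`IncidenceTable`.

    Blank lines and lines starting with ``#`` are skipped; a first line whose
    fields are ``herb_id``/``ingredient_id`` (any case) is treated as the
    header.  Rows must have exactly two non-empty fields; duplicates are
    collapsed and their count logged.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"incidence file not found: {path}")
    rows: list[tuple[str, str]] = []
    n_raw = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if lineno == 1 and [f.lower() for f in fields[:2]] == [
                "herb_id",
                "ingredient_id",
            ]:
                continue
            fields = [f for f in fields if f]
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 non-empty fields, got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
            n_raw += 1
    table = IncidenceTable(rows)
    n_dup = n_raw - len(table)
    if n_dup:
        logger.info("load_incidence: collapsed %d duplicate rows", n_dup)
    return table


def build_bipartite(table: IncidenceTable) -> BipartiteGraph:
    """Build the bipartite graph from an incidence table."""
    if len(table) == 0:
        raise EmptyInputError("cannot build a bipartite graph from an empty table")
    g = nx.Graph()
    for h, i in table.rows:
        g.add_node(("A", h), bipartite=0)
        g.add_node(("B", i), bipartite=1)
        g.add_edge(("A", h), ("B", i))
    return BipartiteGraph(g)


def giant_component(bg: BipartiteGraph) -> BipartiteGraph:
    """Induced subgraph on the largest connected component.

    Ties on size are broken in favour of the component containing the
    lexicographically smallest node identifier.  Discarded component count
    and sizes are logged.
    """
    if bg.n_nodes == 0:
        raise EmptyInputError("giant_component of an empty graph")
    comps = list(nx.connected_components(bg.graph))
    comps.sort(key=lambda c: (-len(c), min(i for _, i in c)))
    giant = comps[0]
    if len(comps) > 1:
        logger.info(
            "giant_component: kept %d nodes, discarded %d components of sizes %s",
            len(giant),
            len(comps) - 1,
            sorted((len(c) for c in comps[1:]), reverse=True),
        )
    return BipartiteGraph(bg.graph.subgraph(giant).copy())


def project(bg: BipartiteGraph, side: str) -> nx.Graph:
    """Weighted unipartite projection of ``bg`` onto one side.

    Nodes ``u, v`` of the chosen side are joined iff they share at least one
    opposite-side neighbour; the edge weight is the shared-neighbour count.
    Nodes without any projection edge are retained as isolates.
    """
    try:
        side = SIDE_ALIASES[side]
    except KeyError:
        raise ValueError(f"unknown side {side!r}; use 'herb'/'A' or 'ingredient'/'B'")
    if bg.n_nodes == 0:
        raise EmptyInputError("cannot project an empty graph")
    keep = sorted(i for s, i in bg.graph.nodes if s == side)
    other_tag = "B" if side == "A" else "A"
    other = sorted(i for s, i in bg.graph.nodes if s == other_tag)
    col = {i: j for j, i in enumerate(other)}
    # biadjacency: rows = chosen side, cols = opposite side
    rows, cols = [], []
    for r, node in enumerate(keep):
        for nb in bg.graph.neighbors((side, node)):
            rows.append(r)
            cols.append(col[nb[1]])
    B = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(keep), len(other))
    )
    A = BipartiteProjection().fit_transform(B)
    g = nx.Graph()
    g.add_nodes_from(keep)
    coo = A.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if i < j:
            g.add_edge(keep[i], keep[j], weight=int(w))
    return g


def degree_stats(g: nx.Graph) -> tuple[dict, float, float]:
    """Unweighted degrees with their mean and the network heterogeneity.

    Heterogeneity is the square root of the population variance of the
    degrees divided by their mean; it is undefined (raises) when the mean
    degree is zero.
    """
    if g.number_of_nodes() == 0:
        raise EmptyInputError("degree_stats of an empty graph")
    degrees = dict(g.degree())
    vals = np.array(list(degrees.values()), dtype=float)
    mean = float(vals.mean())
    if mean == 0:
        raise NoEdgesError("heterogeneity undefined: all nodes are isolates")
    heterogeneity = float(np.sqrt(vals.var()) / mean)
    return degrees, mean, heterogeneity


def write_projection(g: nx.Graph, path: str | Path, delimiter: str = "\t") -> None:
    """Write a projected graph as a weighted edge-list TSV (u, v, weight)."""
    with open(path, "w") as fh:
        fh.write(f"source{delimiter}target{delimiter}weight\n")
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges):
            fh.write(f"{u}{delimiter}{v}{delimiter}{g[u][v]['weight']}\n")


def read_projection(path: str | Path, delimiter: str = "\t") -> nx.Graph:
    """Read a weighted edge-list TSV written by :func:`write_projection`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"graph file not found: {path}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if lineno == 1 and fields[0].lower() in {"source", "u", "node1"}:
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 fields")
            w = int(float(fields[2])) if len(fields) > 2 and fields[2] else 1
            g.add_edge(fields[0], fields[1], weight=w)
    return g
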