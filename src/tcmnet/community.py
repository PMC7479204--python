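"""Modularity scoring, greedy community detection, and partition utilities.

Modularity follows the Newman-Girvan weighted form

    Q = sum_c [ w_c / W  -  (s_c / 2W)^2 ]

with ``W`` the total edge weight, ``w_c`` the intra-community weight and
``s_c`` the summed weighted degree (strength) of community ``c``.  The
built-in detector is the deterministic greedy agglomeration of
:class:`tcmnet.estimators.FastGreedyCommunities`; alternative partitioners
(e.g. infomap or walktrap run elsewhere) plug in through a registry or as
partition CSV files and are rescored with the same Q for an honest
comparison by mean modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import CoverageError, NoEdgesError, ParseError, RegistryError
from .estimators import FastGreedyCommunities, _modularity_from_labels


@dataclass
class Partition:
    """Node -> community assignment with its modularity score.

    Labels are contiguous integers ``0..k-1``.  ``communities`` derives the
    per-label member lists.
    """

    assignment: dict[str, int]
    modularity: float
    algorithm: str = "unknown"

    def __post_init__(self):
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(len(labels))):
            # relabel contiguously, ordered by smallest member id
            order = {}
            for lab in labels:
                order[lab] = min(n for n, l in self.assignment.items() if l == lab)
            remap = {
                lab: i
                for i, lab in enumerate(sorted(labels, key=lambda l: order[l]))
            }
            self.assignment = {n: remap[l] for n, l in self.assignment.items()}

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, lab in self.assignment.items():
            out.setdefault(lab, []).append(node)
        return {lab: sorted(members) for lab, members in sorted(out.items())}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id,community\n")
            for node in sorted(self.assignment):
                fh.write(f"{node},{self.assignment[node]}\n")

    @classmethod
    def read(cls, path: str | Path, algorithm: str = "file") -> "Partition":
        path = Path(path)
        if not path.exists():
            raise ParseError(f"partition file not found: {path}")
        df = pd.read_csv(path, dtype={0: str})
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected columns node_id, community")
        assignment = {
            str(n): int(c) for n, c in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
        return cls(assignment=assignment, modularity=float("nan"), algorithm=algorithm)


def _adjacency(g: nx.Graph, nodes: list, weighted: bool = True) -> sp.csr_matrix:
    A = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    A = sp.csr_matrix(A)
    if not weighted:
        A = sp.csr_matrix((A > 0).astype(float))
    return A


def score_modularity(
    g: nx.Graph, assignment: Mapping[str, int], weighted: bool = True
) -> float:
    """Newman-Girvan Q of ``assignment`` on ``g`` (weight-1 edges if unweighted)."""
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise CoverageError(
            f"{len(missing)} node(s) missing from the partition, e.g. {missing[0]!r}"
        )
    if g.number_of_edges() == 0:
        raise NoEdgesError("modularity undefined on an edgeless graph")
    nodes = sorted(g.nodes)
    labels = np.array([assignment[n] for n in nodes])
    return _modularity_from_labels(_adjacency(g, nodes, weighted), labels)


def fast_greedy(g: nx.Graph, weighted: bool = True) -> Partition:
    """Greedy agglomerative modularity optimisation (CNM) on a projection.

    Deterministic: nodes are processed in sorted-id order, and delta-Q ties
    break toward the lexicographically smallest community-label pair.
    """
    if g.number_of_edges() == 0:
        raise NoEdgesError("fast greedy requires at least one edge")
    nodes = sorted(g.nodes)
    est = FastGreedyCommunities(weighted=weighted).fit(_adjacency(g, nodes, weighted))
    assignment = {n: int(l) for n, l in zip(nodes, est.labels_)}
    return Partition(
        assignment=assignment,
        modularity=float(est.modularity_),
        algorithm="fast_greedy",
    )


# -- partitioner registry ----------------------------------------------------

PARTITIONERS: dict[str, Callable[[nx.Graph], Partition]] = {
    "fast_greedy": fast_greedy,
}


def register_partitioner(name: str, fn: Callable[[nx.Graph], Partition]) -> None:
    """Register an external community-detection algorithm by name."""
    PARTITIONERS[name] = fn


def compare_partitions(
    graphs: Mapping[str, nx.Graph],
    algos: Sequence[str] | Mapping[str, Mapping[str, Partition]],
    weighted: bool = True,
) -> pd.DataFrame:
    """Score algorithms across graphs by modularity; rank by mean Q.

    ``algos`` is either a list of registered partitioner names, or a mapping
    ``algo -> {graph_name -> Partition}`` for partitions produced externally
    (e.g. loaded from CSV).  Every partition is rescored with
    :func:`score_modularity` so the comparison is on a common footing.
    Returns a DataFrame indexed by algorithm with one column per graph plus a
    ``mean_q`` column, sorted by descending mean.
    """
    rows = {}
    if isinstance(algos, Mapping):
        for name, parts in algos.items():
            rows[name] = {
                gname: score_modularity(graphs[gname], parts[gname].assignment, weighted)
                for gname in graphs
            }
    else:
        for name in algos:
            if name not in PARTITIONERS:
                raise RegistryError(
                    f"unknown algorithm {name!r}; registered: {sorted(PARTITIONERS)}"
                )
            fn = PARTITIONERS[name]
            rows[name] = {
                gname: score_modularity(g, fn(g).assignment, weighted)
                for gname, g in graphs.items()
            }
    df = pd.DataFrame(rows).T
    df["mean_q"] = df.mean(axis=1)
    return df.sort_values("mean_q", ascending=False)


@dataclass
class ReducedGraph:
    """Community-level summary graph.

    Nodes are community labels carrying their size and intra-community
    weight; edges carry the summed inter-community weight.
    """

    graph: nx.Graph = field(repr=False)

    @property
    def total_weight(self) -> float:
        intra = sum(d["intra_weight"] for _, d in self.graph.nodes(data=True))
        inter = sum(d["weight"] for _, _, d in self.graph.edges(data=True))
        return intra + inter


def reduce_graph(g: nx.Graph, p: Partition) -> ReducedGraph:
    """Collapse each community of ``p`` to a single node.

    Inter-community edge weights are summed; each node records the community
    size and the intra-community weight, so total weight is conserved.
    """
    missing = [n for n in g.nodes if n not in p.assignment]
    if missing:
        raise CoverageError(f"{len(missing)} node(s) missing from the partition")
    rg = nx.Graph()
    for lab, members in p.communities.items():
        rg.add_node(lab, size=len(members), intra_weight=0.0)
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        cu, cv = p.assignment[u], p.assignment[v]
        if cu == cv:
            rg.nodes[cu]["intra_weight"] += w
        else:
            if rg.has_edge(cu, cv):
                rg[cu][cv]["weight"] += w
            else:
                rg.add_edge(cu, cv, weight=w)
    return ReducedGraph(rg)
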