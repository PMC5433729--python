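"""Population networks from genetic distances.

The third step of the pipeline turns the relationship matrix into a
high-resolution population network: genetic distances ``D = 1 - G``, a
k-nearest-neighbour graph (k = 10 by default, mutual by default), node
annotation with contribution scores and admixture proportions, and GraphML /
edge-list export for standard graph tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]
    n_clamped: int = 0  # entries with G > 1 clamped to distance 0


def distance_matrix(G: RelationshipMatrix) -> DistanceMatrix:
    """Entrywise ``1 - G``; negative distances (G > 1, e.g. inbred
    diagonals) are clamped to zero and counted."""
    d = 1.0 - G.values
    clamped = int((d < 0).sum())
    return DistanceMatrix(np.clip(d, 0.0, None), list(G.ids), clamped)


def knn_graph(D: DistanceMatrix, k: int = 10, mode: str = "mutual") -> nx.Graph:
    """k-nearest-neighbour graph on genetic distances.

    Each node's k nearest neighbours (self excluded, ties broken by input
    order) define directed links; ``mode="mutual"`` keeps edge (i, j) only
    when each endpoint is among the other's k nearest, ``mode="union"``
    keeps it when either is.  Edge attribute ``distance`` carries D_ij.
    """
    n = len(D.ids)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    if mode not in ("mutual", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    d = D.values.copy()
    np.fill_diagonal(d, np.inf)
    # stable ties: argsort on (distance, index)
    neighbor = np.argsort(d, axis=1, kind="stable")[:, :k]
    is_nn = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    is_nn[rows, neighbor.ravel()] = True
    keep = (is_nn & is_nn.T) if mode == "mutual" else (is_nn | is_nn.T)
    graph = nx.Graph(knn=k, mode=mode)
    graph.add_nodes_from(D.ids)
    for i, j in zip(*np.nonzero(np.triu(keep, 1))):
        graph.add_edge(D.ids[i], D.ids[j], distance=float(D.values[i, j]))
    return graph


def annotate_nodes(
    graph: nx.Graph,
    gc: pd.Series | dict | None = None,
    admixture: pd.DataFrame | None = None,
    key_set: set[str] | None = None,
    renorm_tol: float = 1e-6,
) -> nx.Graph:
    """Attach contribution scores, admixture proportions and key flags.

    ``admixture`` is indexed by individual id with one column per ancestral
    population; rows must sum to 1 within ``renorm_tol`` (they are
    renormalized with a warning otherwise).  Missing tables are skipped; ids
    in a table that are not graph nodes raise KeyError.
    """
    import warnings

    if gc is not None:
        gc = pd.Series(gc)
        unknown = set(gc.index) - set(graph.nodes)
        if unknown:
            raise KeyError(f"gc ids not in network: {sorted(unknown)[:3]}")
        nx.set_node_attributes(graph, {x: float(v) for x, v in gc.items()}, "gc")
    if admixture is not None:
        unknown = set(admixture.index) - set(graph.nodes)
        if unknown:
            raise KeyError(f"admixture ids not in network: {sorted(unknown)[:3]}")
        sums = admixture.sum(axis=1)
        if (np.abs(sums - 1.0) > renorm_tol).any():
            warnings.warn("admixture rows do not sum to 1; renormalizing")
            admixture = admixture.div(sums, axis=0)
        for pop in admixture.columns:
            nx.set_node_attributes(
                graph,
                {x: float(v) for x, v in admixture[pop].items()},
                f"ancestry_{pop}",
            )
    if key_set is not None:
        nx.set_node_attributes(graph, {x: x in key_set for x in graph.nodes}, "key_contributor")
    return graph


def export_graph(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write GraphML (default) or a (id1, id2, distance) edge TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "edge-tsv" if path.suffix in (".tsv", ".txt") else "graphml"
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("id1\tid2\tdistance\n")
            for i, j, data in graph.edges(data=True):
                fh.write(f"{i}\t{j}\t{data.get('distance', '')}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
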