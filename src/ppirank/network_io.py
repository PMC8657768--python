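"""Reading, writing and basic manipulation of PPI networks and gene-label lists.

The central container is :class:`Graph`, a plain undirected, unweighted
adjacency structure with contiguous integer node indices mapped to gene
identifier strings.  All downstream stages (random walks, embedding, ranking)
operate on node indices; identifier strings appear only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GeneLabelSet",
    "graph_from_edges",
    "load_edge_list",
    "write_edge_list",
    "load_gene_scores",
    "write_gene_scores",
    "induced_largest_component",
    "export_annotated_subnetwork",
]


@dataclass(frozen=True, eq=False)
class Graph:
    """Undirected, unweighted graph with string node identifiers.

    Attributes
    ----------
    node_ids : tuple of str
        Gene identifiers in first-appearance order; index in this tuple is
        the internal node index.
    adjacency : tuple of numpy int arrays
        ``adjacency[i]`` holds the sorted neighbor indices of node ``i``.
    """

    node_ids: tuple[str, ...]
    adjacency: tuple[np.ndarray, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.node_ids)}
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def index_of(self, gene_id: str) -> int:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def has_edge(self, i: int, j: int) -> bool:
        a = self.adjacency[i]
        k = int(np.searchsorted(a, j))
        return k < len(a) and a[k] == j

    def edges(self) -> Iterable[tuple[int, int]]:
        """Yield each undirected edge once as (i, j) with i < j."""
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i < j:
                    yield i, int(j)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.node_ids == other.node_ids and all(
            np.array_equal(a, b) for a, b in zip(self.adjacency, other.adjacency)
        )

    def __hash__(self) -> int:
        return hash(self.node_ids)

    def validate(self) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        assert len(set(self.node_ids)) == self.n_nodes, "duplicate node ids"
        for i, a in enumerate(self.adjacency):
            assert np.all(np.diff(a) > 0), f"adjacency[{i}] not sorted-unique"
            assert i not in a, f"self-loop at node {i}"
            for j in a:
                assert self.has_edge(int(j), i), f"asymmetric edge ({i},{j})"


@dataclass(frozen=True)
class GeneLabelSet:
    """Known disease genes with optional association scores in [0, 1]."""

    positive_ids: frozenset[str]
    scores: Mapping[str, float] | None = None

    def __len__(self) -> int:
        return len(self.positive_ids)

    def intersect_graph(self, graph: Graph) -> "GeneLabelSet":
        """Drop label genes absent from the graph, warning about each loss."""
        present = frozenset(g for g in self.positive_ids if g in graph)
        dropped = self.positive_ids - present
        if dropped:
            logger.warning(
                "%d label gene(s) absent from the network were dropped: %s",
                len(dropped),
                ", ".join(sorted(dropped)[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        scores = None
        if self.scores is not None:
            scores = {g: self.scores[g] for g in present}
        return GeneLabelSet(present, scores)


def graph_from_edges(
    edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
) -> Graph:
    """Build a :class:`Graph` from (id, id) pairs.

    Duplicate edges (in either orientation) collapse to one; self-loops are
    dropped.  Node order is first appearance in the edge stream, then any
    ``extra_nodes`` not already seen (these become isolated nodes).
    """
    index: dict[str, int] = {}
    edge_set: set[tuple[int, int]] = set()

    def idx(g: str) -> int:
        if g not in index:
            index[g] = len(index)
        return index[g]

    for u, v in edges:
        iu, iv = idx(u), idx(v)
        if iu == iv:
            continue
        edge_set.add((min(iu, iv), max(iu, iv)))
    for g in extra_nodes:
        idx(g)

    n = len(index)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in edge_set:
        nbrs[i].append(j)
        nbrs[j].append(i)
    adjacency = tuple(np.array(sorted(a), dtype=np.int64) for a in nbrs)
    node_ids = tuple(sorted(index, key=index.__getitem__))
    return Graph(node_ids=node_ids, adjacency=adjacency)


def load_edge_list(path: str | Path, delimiter: str | None = None) -> Graph:
    """Read a two-column edge list (TSV or whitespace-delimited).

    Lines starting with ``#`` are comments.  Extra columns (e.g. weights)
    are ignored; duplicate and reversed-duplicate lines collapse to one
    edge; self-loop lines are dropped.

    Parameters
    ----------
    path : file path
    delimiter : explicit field delimiter, or None for any whitespace.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    return graph_from_edges(edges)


def write_edge_list(graph: Graph, path: str | Path, delimiter: str = "\t") -> None:
    """Write each undirected edge once, as identifier pairs."""
    with open(path, "wt") as fh:
        for i, j in graph.edges():
            fh.write(f"{graph.node_ids[i]}{delimiter}{graph.node_ids[j]}\n")


def load_gene_scores(path: str | Path, threshold: float = 0.1) -> GeneLabelSet:
    """Read a gene-score TSV and keep genes with score >= ``threshold``.

    The file has a header line ``gene_id<TAB>score``.  Duplicate gene ids
    keep the maximum score.  The inclusive comparison retains boundary
    genes sitting exactly at the association-score cutoff.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene_id", "gene", "id"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gene, raw = fields[0], fields[1]
            try:
                s = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from exc
            if gene in scores:
                scores[gene] = max(scores[gene], s)
            else:
                scores[gene] = s
    kept = {g: s for g, s in scores.items() if s >= threshold}
    return GeneLabelSet(frozenset(kept), kept)


def write_gene_scores(labels: GeneLabelSet, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tscore\n")
        for g in sorted(labels.positive_ids):
            s = labels.scores.get(g, 1.0) if labels.scores else 1.0
            fh.write(f"{g}\t{s:g}\n")


def induced_largest_component(graph: Graph, keep: Iterable[str]) -> Graph:
    """Largest connected component of the subgraph induced on ``keep``.

    Ties in component size break toward the component containing the
    smallest node index.  An empty ``keep`` yields an empty graph.
    """
    keep_idx = sorted(graph.index_of(g) for g in keep)
    if not keep_idx:
        return Graph(node_ids=(), adjacency=())
    keep_set = set(keep_idx)

    seen: set[int] = set()
    best: list[int] = []
    for start in keep_idx:  # ascending index order makes the tie rule automatic
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph.adjacency[u]:
                v = int(v)
                if v in keep_set and v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        if len(comp) > len(best):
            best = comp

    comp_ids = [graph.node_ids[i] for i in sorted(best)]
    edges = [
        (graph.node_ids[i], graph.node_ids[int(j)])
        for i in sorted(best)
        for j in graph.adjacency[i]
        if int(j) in set(best) and i < int(j)
    ]
    return graph_from_edges(edges, extra_nodes=comp_ids)


def export_annotated_subnetwork(
    sub: Graph,
    annotations: Mapping[str, str],
    edge_path: str | Path,
    node_path: str | Path,
) -> None:
    """Write a subnetwork as an edge TSV plus a node-annotation TSV.

    ``annotations`` maps gene id -> label (``known`` / ``predicted``).
    """
    write_edge_list(sub, edge_path)
    with open(node_path, "wt") as fh:
        fh.write("gene_id\tlabel\n")
        for g in sub.node_ids:
            fh.write(f"{g}\t{annotations.get(g, 'predicted')}\n")
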