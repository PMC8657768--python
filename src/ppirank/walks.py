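"""Random-walk corpus generation: uniform (DeepWalk) and biased (Node2vec).

A walk corpus is to a graph what a sentence corpus is to a language: fixed
length sequences of nodes whose co-occurrence statistics encode topology.
Second-order (Node2vec) walks bias each step by the return parameter ``p``
and the in-out parameter ``q``; with ``p = q = 1`` the walk reduces exactly
to the uniform-neighbor walk of DeepWalk.

Sampling uses the alias method: O(k) table construction, O(1) per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network_io import Graph

__all__ = [
    "AliasTable",
    "WalkConfig",
    "WalkCorpus",
    "build_alias_table",
    "alias_draw",
    "node2vec_transition_weights",
    "generate_walks",
    "save_corpus",
    "load_corpus",
]


@dataclass(frozen=True)
class AliasTable:
    """Alias-method tables for a discrete distribution over K outcomes."""

    prob: np.ndarray  # acceptance probability per bucket, in [0, 1]
    alias: np.ndarray  # alias outcome index per bucket

    def __len__(self) -> int:
        return len(self.prob)

    def outcome_probabilities(self) -> np.ndarray:
        """Reconstruct the categorical distribution the table samples from."""
        k = len(self.prob)
        out = self.prob.copy() / k
        np.add.at(out, self.alias, (1.0 - self.prob) / k)
        return out


def build_alias_table(weights: Sequence[float] | np.ndarray) -> AliasTable:
    """Construct alias tables for sampling proportional to ``weights``.

    Raises ValueError if any weight is negative or all are zero.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-D sequence")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")

    k = w.size
    scaled = w * (k / total)
    prob = np.empty(k, dtype=np.float64)
    alias = np.zeros(k, dtype=np.int64)
    small = [i for i in range(k) if scaled[i] < 1.0]
    large = [i for i in range(k) if scaled[i] >= 1.0]
    while small and large:
        s = small.pop()
        l = large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for i in large:
        prob[i] = 1.0
    for i in small:  # numerical leftovers only
        prob[i] = 1.0
    return AliasTable(prob=prob, alias=alias)


def alias_draw(table: AliasTable, rng: np.random.Generator) -> int:
    """One O(1) draw; consumes exactly one integer and one uniform."""
    k = int(rng.integers(len(table.prob)))
    return k if rng.random() < table.prob[k] else int(table.alias[k])


@dataclass(frozen=True)
class WalkConfig:
    """Walk-corpus hyperparameters.

    ``p`` penalizes immediately returning to the previous node (weight
    1/p); ``q`` trades breadth-first against depth-first exploration
    (weight 1/q for nodes not adjacent to the previous one).  Defaults
    num_walks_per_node=10, walk_length=80 follow the conventions of the
    original random-walk embedding literature.
    """

    num_walks_per_node: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 1.0
    seed: int = 0
    # internal switch: precompute per-directed-edge alias tables when the
    # graph has at most this many directed edges, else compute per step.
    precompute_edge_cutoff: int = 2_000_000

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 1 or self.num_walks_per_node < 1:
            raise ValueError("walk_length and num_walks_per_node must be >= 1")


@dataclass(frozen=True)
class WalkCorpus:
    """A sequence of node-index walks over a graph with ``n_nodes`` nodes."""

    walks: tuple[tuple[int, ...], ...]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.walks)

    def node_frequencies(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for w in self.walks:
            np.add.at(counts, np.fromiter(w, dtype=np.int64), 1)
        return counts


def node2vec_transition_weights(
    prev: int | None, cur: int, graph: Graph, p: float, q: float
) -> np.ndarray:
    """Unnormalized step weights over the sorted neighbors of ``cur``.

    For neighbor x: 1/p if x is the previous node, 1 if x is also a
    neighbor of the previous node, 1/q otherwise.  On the first step
    (``prev is None``) all neighbors get weight 1.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    nbrs = graph.adjacency[cur]
    if prev is None:
        return np.ones(len(nbrs), dtype=np.float64)
    prev_nbrs = graph.adjacency[prev]
    w = np.full(len(nbrs), 1.0 / q, dtype=np.float64)
    # shared-neighbor test by binary search into the sorted prev adjacency
    pos = np.searchsorted(prev_nbrs, nbrs)
    shared = (pos < len(prev_nbrs)) & (prev_nbrs[np.minimum(pos, len(prev_nbrs) - 1)] == nbrs)
    w[shared] = 1.0
    w[nbrs == prev] = 1.0 / p
    return w


def _first_order_tables(graph: Graph) -> list[AliasTable | None]:
    return [
        build_alias_table(np.ones(len(a))) if len(a) else None
        for a in graph.adjacency
    ]


def generate_walks(graph: Graph, config: WalkConfig) -> WalkCorpus:
    """Generate ``num_walks_per_node`` walks from every node.

    Start order is shuffled per pass; each step samples from the biased
    transition distribution via alias tables.  Isolated start nodes yield
    length-1 walks.  Deterministic given (graph, config): all randomness
    derives from a single generator seeded with ``config.seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    first_order = _first_order_tables(graph)
    uniform_case = config.p == 1.0 and config.q == 1.0

    n_directed = 2 * graph.n_edges
    edge_tables: dict[tuple[int, int], AliasTable] = {}
    if not uniform_case and n_directed <= config.precompute_edge_cutoff:
        for u in range(graph.n_nodes):
            for v in graph.adjacency[u]:
                v = int(v)
                edge_tables[(u, v)] = build_alias_table(
                    node2vec_transition_weights(u, v, graph, config.p, config.q)
                )

    walks: list[tuple[int, ...]] = []
    nodes = np.arange(graph.n_nodes)
    for _ in range(config.num_walks_per_node):
        order = rng.permutation(nodes)
        for start in order:
            start = int(start)
            walk = [start]
            if first_order[start] is None:
                walks.append(tuple(walk))
                continue
            prev: int | None = None
            cur = start
            while len(walk) < config.walk_length:
                nbrs = graph.adjacency[cur]
                if prev is None or uniform_case:
                    table = first_order[cur]
                else:
                    table = edge_tables.get((prev, cur))
                    if table is None:
                        table = build_alias_table(
                            node2vec_transition_weights(
                                prev, cur, graph, config.p, config.q
                            )
                        )
                nxt = int(nbrs[alias_draw(table, rng)])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append(tuple(walk))
    return WalkCorpus(walks=tuple(walks), n_nodes=graph.n_nodes)


def save_corpus(corpus: WalkCorpus, graph: Graph, path: str | Path) -> None:
    """Dump one walk per line as space-separated gene identifiers."""
    with open(path, "wt") as fh:
        for w in corpus.walks:
            fh.write(" ".join(graph.node_ids[i] for i in w) + "\n")


def load_corpus(path: str | Path, graph: Graph) -> WalkCorpus:
    walks: list[tuple[int, ...]] = []
    with open(path, "rt") as fh:
        for line in fh:
            ids = line.split()
            if ids:
                walks.append(tuple(graph.index_of(g) for g in ids))
    return WalkCorpus(walks=tuple(walks), n_nodes=graph.n_nodes)
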