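"""Synthetic community-structured networks with planted disease genes.

A planted-partition (stochastic block model) graph stands in for a real
protein-interaction network: within-block edges are denser than
between-block edges, so block membership is exactly the kind of
neighborhood signal that guilt-by-association methods exploit.  Labeling
a fraction of one block as "known disease genes" yields a test bed where
ground truth is known and signal strength is tunable via
(p_in, p_out, fraction).

Fixtures emit the same edge-list and gene-score TSV dialects as
``network_io``, so they exercise the real readers end to end.
"""

from __future__ import annotations

import numpy as np

from .network_io import GeneLabelSet, Graph, graph_from_edges

__all__ = ["sbm_graph", "block_members", "planted_positive_labels"]


def _node_name(block: int, j: int) -> str:
    return f"b{block}_g{j:04d}"


def sbm_graph(
    block_sizes: tuple[int, ...] | list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> Graph:
    """Planted-partition random graph.

    Each within-block node pair is an edge with probability ``p_in``,
    each between-block pair with ``p_out``; requires
    0 <= p_out < p_in <= 1.  Node ids encode block membership
    (``b<block>_g<index>``).  Deterministic given the seed.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if any(s < 1 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.Generator(np.random.PCG64(seed))

    names: list[str] = []
    block_of: list[int] = []
    for bi, size in enumerate(block_sizes):
        for j in range(size):
            names.append(_node_name(bi, j))
            block_of.append(bi)
    n = len(names)
    block_of_arr = np.array(block_of)

    edges: list[tuple[str, str]] = []
    # Bernoulli trial per upper-triangle pair, vectorized row by row
    for i in range(n - 1):
        probs = np.where(block_of_arr[i + 1 :] == block_of[i], p_in, p_out)
        hits = np.nonzero(rng.random(n - i - 1) < probs)[0]
        for h in hits:
            edges.append((names[i], names[i + 1 + int(h)]))
    return graph_from_edges(edges, extra_nodes=names)


def block_members(graph: Graph, block_index: int) -> list[str]:
    """Node ids of one block of an ``sbm_graph`` (by id convention)."""
    prefix = f"b{block_index}_"
    return [g for g in graph.node_ids if g.startswith(prefix)]


def planted_positive_labels(
    graph: Graph,
    block_index: int,
    fraction: float,
    holdout: float = 0.0,
    seed: int = 0,
) -> tuple[GeneLabelSet, GeneLabelSet]:
    """Sample known-gene labels from one block, with an optional holdout.

    ``fraction`` of the target block is sampled as positives; a
    ``holdout`` share of those is split off as hidden test positives
    (excluded from training, used to measure ranking recovery).  The two
    sets are disjoint; training positives must be non-empty.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if not (0.0 <= holdout <= 1.0):
        raise ValueError("holdout must be in [0, 1]")
    members = block_members(graph, block_index)
    if not members:
        raise ValueError(f"block {block_index} has no members")
    rng = np.random.Generator(np.random.PCG64(seed))
    n_pos = int(round(fraction * len(members)))
    if n_pos < 1:
        raise ValueError("fraction selects no positives")
    chosen = [members[i] for i in rng.choice(len(members), size=n_pos, replace=False)]
    n_hold = int(round(holdout * n_pos))
    held = frozenset(chosen[:n_hold])
    train = frozenset(chosen[n_hold:])
    if not train:
        raise ValueError("holdout leaves no training positives")
    return (
        GeneLabelSet(train, {g: 1.0 for g in train}),
        GeneLabelSet(held, {g: 1.0 for g in held}),
    )
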