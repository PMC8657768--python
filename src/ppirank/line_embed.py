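"""LINE embeddings by edge sampling.

LINE optimizes first-order proximity (directly connected nodes get
similar vectors) and/or second-order proximity (nodes with similar
neighborhoods get similar vectors, via a separate context table).  Each
SGD step samples an edge and K noise nodes from a smoothed
degree distribution.  ``order="concat"`` trains both objectives at half
the target dimension and concatenates the row-normalized halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sgd_kernels import sgd_epoch
from .embedding import EmbeddingMatrix
from .network_io import Graph
from .walks import build_alias_table

__all__ = ["LINEConfig", "line_loss_and_grad", "train_line"]


@dataclass(frozen=True)
class LINEConfig:
    """LINE hyperparameters.

    ``samples`` is the total number of edge draws; None means
    100 x n_edges.  ``order`` is "first", "second" or "concat" (concat
    requires an even ``dim``: dim/2 per objective).
    """

    dim: int = 128
    order: str = "concat"
    samples: int | None = None
    negatives: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("first", "second", "concat"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.order == "concat" and self.dim % 2 != 0:
            raise ValueError("order='concat' requires an even dim")
        if self.dim < 1 or self.negatives < 1:
            raise ValueError("dim and negatives must be positive")


def line_loss_and_grad(
    vertex_vec: np.ndarray,
    partner_vec: np.ndarray,
    negative_vecs: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample LINE objective and exact gradients.

    For a sampled edge (i, j): L = -log sigma(t_j . u_i)
    - sum_k log sigma(-t_k . u_i), where t is the vertex table itself for
    first-order proximity and the context table for second-order.
    Returns (loss, grad_vertex, grad_partner, grad_negatives).
    """
    u = np.asarray(vertex_vec, dtype=np.float64)
    t = np.asarray(partner_vec, dtype=np.float64)
    t_neg = np.atleast_2d(np.asarray(negative_vecs, dtype=np.float64))
    if u.shape != t.shape or t_neg.shape[1] != u.shape[0]:
        raise ValueError("all vectors must share one dimension")
    s_pos = 1.0 / (1.0 + np.exp(-t @ u))
    s_neg = 1.0 / (1.0 + np.exp(-(t_neg @ u)))
    loss = -np.log(max(s_pos, 1e-300)) - np.sum(np.log(np.maximum(1.0 - s_neg, 1e-300)))
    grad_vertex = (s_pos - 1.0) * t + s_neg @ t_neg
    grad_partner = (s_pos - 1.0) * u
    grad_negatives = s_neg[:, None] * u[None, :]
    return float(loss), grad_vertex, grad_partner, grad_negatives


def _train_single_order(
    graph: Graph, dim: int, order: str, config: LINEConfig, seed: int
) -> np.ndarray:
    n = graph.n_nodes
    rng = np.random.Generator(np.random.PCG64(seed))
    u = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    if order == "second":
        ctx = np.zeros((n, dim), dtype=np.float64)
    else:
        ctx = u  # shared table: updates on either side act on the same rows

    edges = np.array(list(graph.edges()), dtype=np.int64)
    n_samples = config.samples if config.samples is not None else 100 * len(edges)
    noise = build_alias_table(np.maximum(graph.degrees(), 1e-12) ** 0.75)

    # sample edges up front (seeded); each undirected edge is trained in a
    # random orientation so both endpoints act as vertex and partner
    draw = rng.integers(0, len(edges), size=n_samples)
    flip = rng.integers(0, 2, size=n_samples).astype(bool)
    src = np.where(flip, edges[draw, 1], edges[draw, 0])
    dst = np.where(flip, edges[draw, 0], edges[draw, 1])

    state = np.array([max(1, (seed * 2654435761 + 97) % (1 << 63))], dtype=np.uint64)
    sgd_epoch(
        u,
        ctx,
        np.ascontiguousarray(src),
        np.ascontiguousarray(dst),
        noise.prob,
        noise.alias,
        config.negatives,
        config.learning_rate,
        config.min_learning_rate,
        0,
        n_samples,
        state,
    )
    return u


def train_line(graph: Graph, config: LINEConfig) -> EmbeddingMatrix:
    """Train LINE on a graph; deterministic given ``config.seed``."""
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if config.order == "concat":
        half = config.dim // 2
        u1 = _train_single_order(graph, half, "first", config, config.seed)
        u2 = _train_single_order(graph, half, "second", config, config.seed + 1)
        vec = np.hstack([u1, u2])
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        vec = vec / np.where(norms == 0, 1.0, norms)
    else:
        vec = _train_single_order(
            graph, config.dim, config.order, config, config.seed
        )
    return EmbeddingMatrix(ids=graph.node_ids, vectors=vec)
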