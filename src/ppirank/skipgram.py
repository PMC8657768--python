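"""Skip-gram with negative sampling (SGNS) trained on walk corpora.

Walks play the role of sentences: each node is predicted from the nodes
co-occurring within a context window, against noise nodes drawn from a
smoothed unigram distribution.  The input-vector (hidden-layer) table is
the exported node embedding; it serves both DeepWalk (uniform walks) and
Node2vec (biased walks), which differ only in how the corpus was made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sgd_kernels import sgd_epoch
from .embedding import EmbeddingMatrix
from .walks import WalkCorpus, build_alias_table

__all__ = [
    "SGNSConfig",
    "build_training_pairs",
    "sgns_loss_and_grad",
    "train_sgns",
]


@dataclass(frozen=True)
class SGNSConfig:
    """SGNS hyperparameters.

    Defaults are the canonical word2vec choices: window 10, 5 negatives
    per positive pair, 5 epochs, learning rate 0.025 decayed linearly to
    1e-4, noise distribution proportional to unigram^0.75.
    """

    dim: int = 128
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    noise_exponent: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dim, self.window, self.negatives, self.epochs) < 1:
            raise ValueError("dim, window, negatives, epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def build_training_pairs(corpus: WalkCorpus, window: int) -> np.ndarray:
    """Enumerate (center, context) pairs within the window.

    For each position t of each walk, emits (walk[t], walk[t+j]) for all
    offsets j in [-window, window], j != 0, that stay in bounds.  Returns
    an (n_pairs, 2) int64 array in corpus order.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for walk in corpus.walks:
        L = len(walk)
        if L < 2:
            continue
        w = np.fromiter(walk, dtype=np.int64, count=L)
        for j in range(1, window + 1):
            if j >= L:
                break
            # pairs at offset +j and -j
            centers.append(w[:-j])
            contexts.append(w[j:])
            centers.append(w[j:])
            contexts.append(w[:-j])
    if not centers:
        return np.empty((0, 2), dtype=np.int64)
    out = np.empty((sum(len(c) for c in centers), 2), dtype=np.int64)
    out[:, 0] = np.concatenate(centers)
    out[:, 1] = np.concatenate(contexts)
    return out


def sgns_loss_and_grad(
    center_vec: np.ndarray,
    context_vec: np.ndarray,
    negative_vecs: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and exact gradients of the SGNS objective for one pair.

    L = -log sigma(u_ctx . v_c) - sum_k log sigma(-u_k . v_c)

    Returns (loss, grad_center, grad_context, grad_negatives).
    """
    v_c = np.asarray(center_vec, dtype=np.float64)
    u_o = np.asarray(context_vec, dtype=np.float64)
    u_neg = np.atleast_2d(np.asarray(negative_vecs, dtype=np.float64))
    if v_c.shape != u_o.shape or u_neg.shape[1] != v_c.shape[0]:
        raise ValueError("all vectors must share one dimension")

    s_pos = 1.0 / (1.0 + np.exp(-u_o @ v_c))
    s_neg = 1.0 / (1.0 + np.exp(-(u_neg @ v_c)))
    loss = -np.log(max(s_pos, 1e-300)) - np.sum(np.log(np.maximum(1.0 - s_neg, 1e-300)))

    grad_center = (s_pos - 1.0) * u_o + s_neg @ u_neg
    grad_context = (s_pos - 1.0) * v_c
    grad_negatives = s_neg[:, None] * v_c[None, :]
    return float(loss), grad_center, grad_context, grad_negatives


def _noise_distribution(corpus: WalkCorpus, exponent: float) -> np.ndarray:
    freq = corpus.node_frequencies().astype(np.float64)
    freq[freq == 0] = 0.0
    w = freq**exponent
    if w.sum() == 0:
        raise ValueError("corpus is empty")
    return w


def train_sgns(
    corpus: WalkCorpus,
    config: SGNSConfig,
    node_ids: tuple[str, ...] | None = None,
    return_losses: bool = False,
):
    """Train SGNS on a walk corpus; returns the input-vector table.

    Input vectors initialize uniformly in [-0.5/d, 0.5/d], context
    vectors at zero (so the first-update loss of an all-zero pair is
    exactly (1 + negatives) * ln 2).  Training is sequential SGD over the
    pair list, shuffled per epoch under the seed; nodes absent from the
    corpus keep their random initialization.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    n_nodes = corpus.n_nodes
    pairs = build_training_pairs(corpus, config.window)
    if pairs.shape[0] == 0:
        raise ValueError("corpus yields no training pairs (all walks length 1)")
    if pairs.max() >= n_nodes:
        raise ValueError("corpus contains node index >= n_nodes")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    d = config.dim
    w_in = rng.uniform(-0.5 / d, 0.5 / d, size=(n_nodes, d))
    w_out = np.zeros((n_nodes, d), dtype=np.float64)

    noise = build_alias_table(_noise_distribution(corpus, config.noise_exponent))
    state = np.array([max(1, config.seed * 2654435761 % (1 << 63))], dtype=np.uint64)

    total = config.epochs * pairs.shape[0]
    losses: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(pairs.shape[0])
        shuffled = pairs[perm]
        mean_loss = sgd_epoch(
            w_in,
            w_out,
            np.ascontiguousarray(shuffled[:, 0]),
            np.ascontiguousarray(shuffled[:, 1]),
            noise.prob,
            noise.alias,
            config.negatives,
            config.learning_rate,
            config.min_learning_rate,
            epoch * pairs.shape[0],
            total,
            state,
        )
        losses.append(float(mean_loss))

    ids = node_ids if node_ids is not None else tuple(str(i) for i in range(n_nodes))
    emb = EmbeddingMatrix(ids=tuple(ids), vectors=w_in)
    if return_losses:
        return emb, losses
    return emb
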