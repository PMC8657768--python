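"""The embedding container and its on-disk text format.

Embeddings are exchanged in the word2vec text format: a header line
``<n_nodes> <dim>`` followed by one ``<gene_id> v1 ... vd`` line per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["EmbeddingMatrix", "save_word2vec", "load_word2vec"]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """One real-valued feature vector per node.

    ``vectors[i]`` is the feature vector of gene ``ids[i]``.
    """

    ids: tuple[str, ...]
    vectors: np.ndarray  # (n_nodes, dim), float64
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_nodes, dim) matching ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")
        if not self._index:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.ids)}
            )

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def vector(self, gene_id: str) -> np.ndarray:
        return self.vectors[self._index[gene_id]]

    def rows_for(self, gene_ids: Iterable[str]) -> np.ndarray:
        return self.vectors[[self._index[g] for g in gene_ids]]


def save_word2vec(emb: EmbeddingMatrix, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"{emb.n_nodes} {emb.dim}\n")
        for g, row in zip(emb.ids, emb.vectors):
            fh.write(g + " " + " ".join(repr(float(x)) for x in row) + "\n")


def load_word2vec(path: str | Path) -> EmbeddingMatrix:
    with open(path, "rt") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        ids: list[str] = []
        vectors = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            fields = fh.readline().split()
            ids.append(fields[0])
            vectors[i] = [float(x) for x in fields[1 : d + 1]]
    return EmbeddingMatrix(ids=tuple(ids), vectors=vectors)
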