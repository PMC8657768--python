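"""End-to-end orchestration: embed -> compress -> evaluate -> rank.

This module is the programmatic counterpart of the command-line
interface: a validated configuration object plus functions that run the
whole workflow or single stages on in-memory objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import pandas as pd

from .autoencoder import StackConfig, encode_stack
from .classify import (
    CLASSIFIER_KINDS,
    MetricsReport,
    assemble_dataset,
    cross_validate,
)
from .embedding import EmbeddingMatrix
from .line_embed import LINEConfig, train_line
from .network_io import GeneLabelSet, Graph
from .rank import train_final_and_score
from .skipgram import SGNSConfig, train_sgns
from .walks import WalkConfig, generate_walks

__all__ = ["EmbedOptions", "PipelineConfig", "embed_graph", "run_pipeline"]

EMBEDDERS = ("deepwalk", "node2vec", "line")


@dataclass(frozen=True)
class EmbedOptions:
    """Knobs shared by the walk-based embedders plus LINE-specific ones."""

    num_walks: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 1.0
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    line_order: str = "concat"
    line_samples: int | None = None


def embed_graph(
    graph: Graph,
    method: str,
    dim: int,
    options: EmbedOptions | None = None,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Embed a graph with deepwalk, node2vec or line.

    DeepWalk is Node2vec at p = q = 1 (uniform walks); both feed a walk
    corpus to skip-gram with negative sampling.  LINE trains directly by
    edge sampling.
    """
    opts = options or EmbedOptions()
    if method not in EMBEDDERS:
        raise ValueError(f"unknown embedder {method!r}; choose from {EMBEDDERS}")
    if method == "line":
        cfg = LINEConfig(
            dim=dim,
            order=opts.line_order,
            samples=opts.line_samples,
            negatives=opts.negatives,
            learning_rate=opts.learning_rate,
            seed=seed,
        )
        return train_line(graph, cfg)
    p, q = (1.0, 1.0) if method == "deepwalk" else (opts.p, opts.q)
    wcfg = WalkConfig(
        num_walks_per_node=opts.num_walks,
        walk_length=opts.walk_length,
        p=p,
        q=q,
        seed=seed,
    )
    corpus = generate_walks(graph, wcfg)
    scfg = SGNSConfig(
        dim=dim,
        window=opts.window,
        negatives=opts.negatives,
        epochs=opts.epochs,
        learning_rate=opts.learning_rate,
        seed=seed,
    )
    return train_sgns(corpus, scfg, node_ids=graph.node_ids)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full run.

    ``stack_dims`` runs from the embedding dimension to the bottleneck;
    leave empty to skip compression.
    """

    embedder: str = "node2vec"
    dim: int = 128
    embed: EmbedOptions = field(default_factory=EmbedOptions)
    stack_dims: tuple[int, ...] = ()
    stack_epochs: int = 100
    stack_activation: str = "sigmoid"
    classifier: str = "svm"
    cv_folds: int = 5
    seed: int = 0

    @staticmethod
    def from_mapping(raw: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a flat key-value mapping, reporting all problems at once."""
        errors: list[str] = []
        known_embed = {f.name for f in fields(EmbedOptions)}
        known_top = {f.name for f in fields(PipelineConfig)} - {"embed"}
        embed_kwargs: dict[str, Any] = {}
        top_kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key in known_embed:
                embed_kwargs[key] = value
            elif key in known_top:
                if key == "stack_dims":
                    if isinstance(value, str):
                        value = tuple(
                            int(v) for v in value.replace(",", " ").split()
                        )
                    else:
                        value = tuple(int(v) for v in value)
                top_kwargs[key] = value
            else:
                errors.append(f"unknown config key: {key}")
        cfg = None
        try:
            cfg = PipelineConfig(embed=EmbedOptions(**embed_kwargs), **top_kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
        if cfg is not None:
            if cfg.embedder not in EMBEDDERS:
                errors.append(f"embedder must be one of {EMBEDDERS}")
            if cfg.classifier not in CLASSIFIER_KINDS:
                errors.append(f"classifier must be one of {CLASSIFIER_KINDS}")
            if cfg.stack_dims and cfg.stack_dims[0] != cfg.dim:
                errors.append(
                    f"stack_dims[0] ({cfg.stack_dims[0]}) must equal dim ({cfg.dim})"
                )
            if cfg.cv_folds < 2:
                errors.append("cv_folds must be >= 2")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        return cfg

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PipelineResult:
    embeddings: EmbeddingMatrix
    compressed: EmbeddingMatrix
    metrics: MetricsReport
    predictions: pd.DataFrame


def run_pipeline(
    graph: Graph, positives: GeneLabelSet, config: PipelineConfig
) -> PipelineResult:
    """Run embed -> encode -> evaluate (k-fold CV) -> predict."""
    positives = positives.intersect_graph(graph)
    emb = embed_graph(
        graph, config.embedder, config.dim, config.embed, seed=config.seed
    )
    if config.stack_dims:
        scfg = StackConfig(
            layer_dims=config.stack_dims,
            activation=config.stack_activation,
            epochs=config.stack_epochs,
            seed=config.seed,
        )
        compressed, _ = encode_stack(emb, scfg)
    else:
        compressed = emb
    data = assemble_dataset(compressed, positives, seed=config.seed)
    metrics = cross_validate(
        data, kind=config.classifier, k=config.cv_folds, seed=config.seed
    )
    predictions = train_final_and_score(
        compressed, positives, classifier=config.classifier, seed=config.seed
    )
    return PipelineResult(
        embeddings=emb,
        compressed=compressed,
        metrics=metrics,
        predictions=predictions,
    )
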