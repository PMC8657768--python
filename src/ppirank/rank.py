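"""Final-model training and genome-wide candidate ranking.

The production step of the framework: train the chosen classifier on all
known disease genes (plus a seeded balanced negative draw) and score
every unlabeled gene.  Genes that served as sampled training negatives
remain in the output — they are still unlabeled, and plausible
candidates — but carry a ``used_as_negative`` flag so training leakage
is visible to the reader of the table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .classify import assemble_dataset, fit_classifier
from .embedding import EmbeddingMatrix
from .network_io import GeneLabelSet, Graph, induced_largest_component

logger = logging.getLogger(__name__)

__all__ = ["train_final_and_score", "top_k", "top_gene_subnetwork"]


def train_final_and_score(
    embeddings: EmbeddingMatrix,
    positives: GeneLabelSet,
    classifier: str = "svm",
    seed: int = 0,
    **hyper,
) -> pd.DataFrame:
    """Rank every unlabeled gene by predicted disease association.

    Returns a DataFrame with columns gene_id, score, rank,
    used_as_negative, sorted by descending score (ties broken by gene
    id).  The ranking is a permutation of the unlabeled gene set and is
    deterministic under fixed seed and configuration.
    """
    data = assemble_dataset(embeddings, positives, seed=seed)
    model = fit_classifier(classifier, data, seed=seed, **hyper)

    unlabeled = [g for g in embeddings.ids if g not in positives.positive_ids]
    if not unlabeled:
        raise ValueError("no unlabeled genes to score")
    negatives_used = {
        g for g, y in zip(data.gene_ids, data.labels) if y == 0
    }
    scores = model.score_samples(embeddings.rows_for(unlabeled))
    df = pd.DataFrame(
        {
            "gene_id": unlabeled,
            "score": scores,
            "used_as_negative": [g in negatives_used for g in unlabeled],
        }
    )
    df = df.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df[["gene_id", "score", "rank", "used_as_negative"]]


def top_k(ranked: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k rows of a ranked table (all rows, with a warning, if k is
    larger than the table)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked):
        logger.warning("requested top %d but table has only %d rows", k, len(ranked))
    return ranked.head(k).reset_index(drop=True)


def top_gene_subnetwork(
    graph: Graph,
    predicted: list[str] | set[str],
    known: list[str] | set[str],
) -> tuple[Graph, dict[str, str]]:
    """Largest connected component induced on predicted + known genes.

    Returns the component subgraph and a gene -> {"known", "predicted"}
    annotation map (known wins when a gene is in both sets).  Ids absent
    from the graph are dropped with a warning.
    """
    predicted = set(predicted)
    known = set(known)
    union = predicted | known
    missing = {g for g in union if g not in graph}
    if missing:
        logger.warning(
            "%d gene(s) not in the network were dropped from the subnetwork",
            len(missing),
        )
    sub = induced_largest_component(graph, union - missing)
    annotations = {
        g: ("known" if g in known else "predicted") for g in sub.node_ids
    }
    return sub, annotations
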