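"""Dataset assembly, classifiers and evaluation metrics.

Known disease genes are positives; an equal number of negatives is drawn
uniformly from the unlabeled genes, giving a balanced binary dataset
over the embedded nodes.  Three classifiers are supported: an RBF-kernel
SVM with Platt-calibrated probability scores, a random forest (both via
scikit-learn, used as commodity classifiers with default settings), and
a natively implemented logistic regression

    p(y=1|x) = 1 / (1 + exp(-(w.x + b)))

fit by penalized maximum likelihood.  All evaluation primitives —
confusion-count metrics, ROC and PR curves with one operating point per
distinct score threshold, and trapezoid-rule AUC — are implemented here
rather than delegated, since their exact formulas define the reported
numbers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .embedding import EmbeddingMatrix
from .network_io import GeneLabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "LogisticParams",
    "MetricsReport",
    "assemble_dataset",
    "logistic_fit",
    "logistic_predict_proba",
    "fit_classifier",
    "confusion_metrics",
    "roc_pr_curves",
    "auc_trapezoid",
    "cross_validate",
]

CLASSIFIER_KINDS = ("svm", "logistic", "random_forest")


@dataclass(frozen=True)
class LabeledDataset:
    """Balanced feature matrix with binary labels over selected genes."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) in {0, 1}
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n_pos = int(self.labels.sum())
        if n_pos * 2 != len(self.labels):
            raise ValueError("dataset must be balanced (equal positives/negatives)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene in dataset")

    @property
    def n(self) -> int:
        return len(self.labels)


def assemble_dataset(
    embeddings: EmbeddingMatrix, positives: GeneLabelSet, seed: int = 0
) -> LabeledDataset:
    """Balanced dataset: all positives plus an equal-size uniform draw of
    negatives from the unlabeled genes (without replacement, seeded)."""
    pos = sorted(g for g in positives.positive_ids if g in embeddings)
    if not pos:
        raise ValueError("no positive gene is present in the embedding")
    unlabeled = [g for g in embeddings.ids if g not in positives.positive_ids]
    if len(unlabeled) < len(pos):
        raise ValueError(
            f"need {len(pos)} negatives but only {len(unlabeled)} unlabeled genes"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    neg_idx = rng.choice(len(unlabeled), size=len(pos), replace=False)
    neg = [unlabeled[i] for i in sorted(neg_idx)]
    ids = tuple(pos + neg)
    features = embeddings.rows_for(ids)
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=np.int64)
    return LabeledDataset(features=features, labels=labels, gene_ids=ids)


# ---------------------------------------------------------------------------
# logistic regression (native)


@dataclass(frozen=True)
class LogisticParams:
    w: np.ndarray
    b: float


def logistic_predict_proba(params: LogisticParams, x: np.ndarray) -> np.ndarray:
    """p(y=1|x) = 1/(1 + exp(-(w.x + b)))."""
    z = np.atleast_2d(x) @ params.w + params.b
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def logistic_fit(
    x: np.ndarray,
    y: np.ndarray,
    regularization: float = 1e-4,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> LogisticParams:
    """Maximize the (ridge-penalized) log-likelihood by gradient ascent.

    The step size adapts: it grows while the objective improves and
    halves on a failed step.  Stops at gradient-norm ``tol``; if the
    budget runs out first a warning is emitted and the best iterate is
    returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, d = x.shape
    w = np.zeros(d)
    b = 0.0

    def objective(w: np.ndarray, b: float) -> float:
        z = x @ w + b
        # log-likelihood: sum y*z - log(1 + e^z), stable form
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
        return ll - 0.5 * regularization * float(w @ w)

    lr = 1.0 / n
    best = objective(w, b)
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-np.clip(x @ w + b, -500, 500)))
        g_w = x.T @ (y - p) - regularization * w
        g_b = float(np.sum(y - p))
        gnorm = float(np.sqrt(g_w @ g_w + g_b * g_b))
        if gnorm < tol:
            converged = True
            break
        w_new = w + lr * g_w
        b_new = b + lr * g_b
        obj = objective(w_new, b_new)
        if obj > best:
            w, b, best = w_new, b_new, obj
            lr *= 1.1
        else:
            lr *= 0.5
            if lr < 1e-16:
                converged = True  # step size exhausted at a stationary point
                break
    if not converged:
        warnings.warn(
            "logistic_fit did not reach gradient tolerance; returning best iterate",
            RuntimeWarning,
        )
    return LogisticParams(w=w, b=b)


# ---------------------------------------------------------------------------
# classifier front-end


class _LogisticModel:
    def __init__(self, regularization: float = 1e-4):
        self.regularization = regularization
        self.params: LogisticParams | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_LogisticModel":
        self.params = logistic_fit(x, y, self.regularization)
        return self

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        return logistic_predict_proba(self.params, x)


class _SklearnProbModel:
    def __init__(self, est):
        self.est = est

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_SklearnProbModel":
        self.est.fit(x, y)
        return self

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        pos = list(self.est.classes_).index(1)
        return self.est.predict_proba(x)[:, pos]


def make_classifier(kind: str, seed: int = 0, **hyper):
    """Instantiate an unfitted classifier exposing fit / score_samples.

    ``svm``: soft-margin RBF-kernel SVM; decision values are mapped to
    probabilities by Platt-style sigmoid calibration, which preserves
    their rank order.  ``random_forest``: mean predicted class
    probability over the tree ensemble.  ``logistic``: the native
    implementation above.  Scores are always in [0, 1].
    """
    if kind == "svm":
        return _SklearnProbModel(
            SVC(kernel=hyper.pop("kernel", "rbf"), probability=True,
                random_state=seed, **hyper)
        )
    if kind == "random_forest":
        return _SklearnProbModel(RandomForestClassifier(random_state=seed, **hyper))
    if kind == "logistic":
        return _LogisticModel(**hyper)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def fit_classifier(kind: str, data: LabeledDataset, seed: int = 0, **hyper):
    """Fit a classifier of the given kind on a balanced dataset."""
    return make_classifier(kind, seed=seed, **hyper).fit(data.features, data.labels)


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Precision, recall/TPR, FPR, accuracy and F1 from confusion counts.

    A metric whose denominator is zero is reported as NaN (undefined),
    never silently as 0.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + tn + fp + fn

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    fpr = ratio(fp, tn + fp)
    acc = ratio(tp + tn, n)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "tpr": recall,
        "fpr": fpr,
        "acc": acc,
        "f1": f1,
    }


def roc_pr_curves(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Operating points of the ROC and PR curves.

    One point per distinct score threshold (predict positive when
    score >= threshold), thresholds descending; ties share a threshold.
    ROC points (FPR, TPR) additionally include the endpoints (0,0) and
    (1,1).  PR points are (recall, precision) at achieved thresholds
    only — no synthetic (0,1) anchor.  Both are returned as (k, 2)
    arrays with non-decreasing x.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative TP / FP after taking the i+1 highest scores
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    # last index of each distinct-threshold group
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]

    tpr = tp_cum[idx] / n_pos
    fpr = fp_cum[idx] / n_neg
    roc = np.column_stack([fpr, tpr])
    if not (roc[0] == (0.0, 0.0)).all():
        roc = np.vstack([[0.0, 0.0], roc])
    if not (roc[-1] == (1.0, 1.0)).all():
        roc = np.vstack([roc, [1.0, 1.0]])

    recall = tp_cum[idx] / n_pos
    precision = tp_cum[idx] / (tp_cum[idx] + fp_cum[idx])
    pr = np.column_stack([recall, precision])
    return roc, pr


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoid-rule area under a curve of (x, y) points:
    0.5 * sum_i (x_{i+1} - x_i) * (y_i + y_{i+1}).  x must be sorted."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need >= 2 (x, y) points")
    dx = np.diff(pts[:, 0])
    if np.any(dx < 0):
        raise ValueError("points must be sorted by non-decreasing x")
    return float(0.5 * np.sum(dx * (pts[:-1, 1] + pts[1:, 1])))


def _score_metrics(scores: np.ndarray, y: np.ndarray) -> dict[str, float]:
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    cm = confusion_metrics(tp, tn, fp, fn)
    roc, pr = roc_pr_curves(scores, y)
    if len(pr) < 2:
        # constant scores: one achieved point (recall 1, prevalence);
        # treat as constant precision over the recall span
        auprc = float(pr[-1, 1])
    else:
        auprc = auc_trapezoid(pr)
    return {
        "acc": cm["acc"],
        "f1": cm["f1"],
        "auroc": auc_trapezoid(roc),
        "auprc": auprc,
    }


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold and mean values of ACC, F1, AUROC, AUPRC."""

    folds: tuple[dict[str, float], ...]

    @property
    def mean(self) -> dict[str, float]:
        keys = self.folds[0].keys()
        return {k: float(np.mean([f[k] for f in self.folds])) for k in keys}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"folds": list(self.folds), "mean": self.mean}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_tsv(self, path: str | Path) -> None:
        keys = ["acc", "f1", "auroc", "auprc"]
        with open(path, "wt") as fh:
            fh.write("fold\t" + "\t".join(keys) + "\n")
            for i, f in enumerate(self.folds, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{f[k]:.6f}" for k in keys) + "\n")
            fh.write("mean\t" + "\t".join(f"{self.mean[k]:.6f}" for k in keys) + "\n")


def cross_validate(
    data: LabeledDataset,
    kind: str = "svm",
    k: int = 5,
    seed: int = 0,
    refresh_negatives: tuple[EmbeddingMatrix, GeneLabelSet] | None = None,
    **hyper,
) -> MetricsReport:
    """Stratified k-fold cross-validation of one classifier.

    Folds are stratified so every fold contains both classes; metrics are
    computed from held-out scores per fold and averaged.  By default
    negatives were drawn once at dataset assembly; passing
    ``refresh_negatives=(embeddings, positives)`` redraws the training
    negatives from the unlabeled pool on every fold instead.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[dict[str, float]] = []
    for fold_i, (train, test) in enumerate(skf.split(data.features, data.labels)):
        x_tr, y_tr = data.features[train], data.labels[train]
        if refresh_negatives is not None:
            emb, positives = refresh_negatives
            in_dataset = set(data.gene_ids)
            pool = [
                g
                for g in emb.ids
                if g not in positives.positive_ids and g not in in_dataset
            ]
            rng = np.random.Generator(np.random.PCG64(seed * 1000 + fold_i))
            n_neg = int(np.sum(y_tr == 0))
            if len(pool) >= n_neg:
                fresh = rng.choice(len(pool), size=n_neg, replace=False)
                x_neg = emb.rows_for([pool[i] for i in sorted(fresh)])
                x_tr = np.vstack([x_tr[y_tr == 1], x_neg])
                y_tr = np.r_[np.ones(int(np.sum(y_tr == 1)), dtype=np.int64),
                             np.zeros(n_neg, dtype=np.int64)]
        model = make_classifier(kind, seed=seed, **hyper).fit(x_tr, y_tr)
        scores = model.score_samples(data.features[test])
        folds.append(_score_metrics(scores, data.labels[test]))
    return MetricsReport(folds=tuple(folds))
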