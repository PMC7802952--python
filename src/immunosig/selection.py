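"""Iterative L1-penalized backward gene elimination with dual model selection.

Starting from the rank-sum-filtered gene pool, an L1-penalized logistic
model over the three immune clusters is refit repeatedly; after each fit
the least important genes (smallest maximum absolute coefficient across
classes) are dropped.  While more than ``phase1_threshold`` coefficients
are nonzero, 10% of the active genes go per iteration; below that, one
gene per iteration, down to a floor of ``phase2_floor`` genes.  Every
iteration is scored on held-out data with a caller-supplied metric, and
the final signature is the active set of the best-scoring iteration:

* accuracy criterion — best Cluster-B-vs-rest validation accuracy
  ("Point A" selection);
* log-rank criterion — smallest log-rank p-value between predicted
  B / not-B survival on validation samples ("Point B" selection).

Ties prefer the smaller gene set (the efficiency objective), then the
earlier iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .survival import logrank

__all__ = [
    "RegressionConfig",
    "WeightMatrix",
    "TraceIteration",
    "SelectionTrace",
    "fit_l1_multinomial",
    "gene_importance",
    "backward_eliminate",
    "predict_clusters",
    "evaluate_accuracy",
    "evaluate_logrank",
    "select_point",
]

logger = logging.getLogger(__name__)

CLUSTERS = ("A", "B", "C")


@dataclass(frozen=True)
class RegressionConfig:
    """L1 logistic settings.

    ``lam`` is the lasso strength; the solver is run with inverse
    regularization C = 1/lam (the penalty multiplies the L1 term added
    to the logistic loss).  One-vs-rest is the multiclass scheme.
    """

    lam: float = 1.0
    multiclass_scheme: str = "ovr"
    max_iterations: int = 1000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.multiclass_scheme != "ovr":
            raise ValueError("only the one-vs-rest scheme is implemented")


@dataclass
class WeightMatrix:
    """Fitted coefficients: genes x classes, plus per-class intercepts."""

    genes: list[str]
    classes: list[str]
    weights: np.ndarray  # (n_genes, n_classes)
    intercepts: np.ndarray  # (n_classes,)

    @property
    def nnz(self) -> int:
        """Genes with at least one nonzero coefficient (intercepts excluded)."""
        return int(np.sum(np.any(self.weights != 0.0, axis=1)))


def fit_l1_multinomial(
    expr: pd.DataFrame, labels, config: RegressionConfig = RegressionConfig()
) -> WeightMatrix:
    """One-vs-rest L1 logistic regression on a genes x samples matrix.

    One liblinear binary problem per observed class; deterministic for a
    fixed seed and data.  Expression is assumed already standardized
    (the pipeline's normalized-matrix convention), so coefficient
    magnitudes are comparable across genes.
    """
    labels = np.asarray(labels)
    present = [c for c in CLUSTERS if c in labels] or sorted(set(labels))
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes to fit")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    n_genes = expr.shape[0]
    weights = np.zeros((n_genes, len(present)))
    intercepts = np.zeros(len(present))
    for ci, cls_name in enumerate(present):
        est = LogisticRegression(
            l1_ratio=1.0,  # pure lasso penalty
            C=1.0 / config.lam,
            solver="liblinear",
            tol=config.tol,
            max_iter=config.max_iterations,
            random_state=config.seed,
        )
        est.fit(X, (labels == cls_name).astype(int))
        if est.n_iter_[0] >= config.max_iterations:
            logger.warning("liblinear did not converge for class %s", cls_name)
        weights[:, ci] = est.coef_[0]
        intercepts[ci] = est.intercept_[0]
    return WeightMatrix(
        genes=list(expr.index), classes=present, weights=weights, intercepts=intercepts
    )


def gene_importance(w: WeightMatrix) -> np.ndarray:
    """Per-gene score: the largest absolute coefficient over classes."""
    return np.max(np.abs(w.weights), axis=1)


@dataclass
class TraceIteration:
    active_genes: list[str]
    weights: WeightMatrix
    metric: float


@dataclass
class SelectionTrace:
    iterations: list[TraceIteration] = field(default_factory=list)
    phase1_end: int | None = None  # first iteration index fitted in phase 2
    point_A: list[str] | None = None
    point_B: list[str] | None = None

    def sizes(self) -> list[int]:
        return [len(it.active_genes) for it in self.iterations]

    def metrics(self) -> list[float]:
        return [it.metric for it in self.iterations]


def removal_count(n_active: int, nnz: int, phase1_threshold: int, removal_rate: float) -> int:
    """How many genes the schedule drops at the current state.

    Phase 1 (nnz above the threshold) drops max(1, floor(rate * active));
    phase 2 drops exactly one.
    """
    if nnz > phase1_threshold:
        return max(1, int(np.floor(removal_rate * n_active)))
    return 1


def backward_eliminate(
    expr: pd.DataFrame,
    labels,
    config: RegressionConfig,
    metric: Callable[[WeightMatrix], float],
    phase1_threshold: int = 900,
    phase2_floor: int = 50,
    removal_rate: float = 0.1,
) -> SelectionTrace:
    """Run the backward-elimination loop and record every iteration.

    ``metric`` scores each fitted model on held-out data (higher or lower
    being better is the selection criterion's concern, not the trace's).
    Elimination stops once the fitted model has ``phase2_floor`` or fewer
    genes with nonzero coefficients; a starting set already at or below
    the floor yields a single-iteration trace.
    """
    active = list(expr.index)
    trace = SelectionTrace()
    if len(active) <= phase2_floor:
        logger.info("starting set of %d genes is at/below the floor; no elimination", len(active))
        w = fit_l1_multinomial(expr, labels, config)
        trace.iterations.append(TraceIteration(list(active), w, float(metric(w))))
        return trace

    while True:
        w = fit_l1_multinomial(expr.loc[active], labels, config)
        trace.iterations.append(TraceIteration(list(active), w, float(metric(w))))
        nnz = w.nnz
        if nnz <= phase1_threshold and trace.phase1_end is None:
            trace.phase1_end = len(trace.iterations) - 1
        if nnz <= phase2_floor or len(active) <= 1:
            break
        k = removal_count(len(active), nnz, phase1_threshold, removal_rate)
        scores = gene_importance(w)
        # stable on score; among ties the LATER gene is dropped first, so
        # earlier signature positions survive longer
        order = np.lexsort((-np.arange(len(active)), scores))
        drop = set(order[:k])
        active = [g for i, g in enumerate(active) if i not in drop]
    return trace


def predict_clusters(w: WeightMatrix, expr: pd.DataFrame) -> np.ndarray:
    """Three-class prediction: argmax of the per-class decision values."""
    X = expr.loc[w.genes].to_numpy(dtype=float).T
    scores = X @ w.weights + w.intercepts
    return np.array(w.classes)[np.argmax(scores, axis=1)]


def evaluate_accuracy(w: WeightMatrix, expr_val: pd.DataFrame, labels_val) -> float:
    """Cluster-B-vs-rest accuracy of the collapsed three-class prediction."""
    labels_val = np.asarray(labels_val)
    if labels_val.size == 0:
        raise ValueError("empty validation set")
    pred_b = predict_clusters(w, expr_val) == "B"
    true_b = labels_val == "B"
    return float(np.mean(pred_b == true_b))


def evaluate_logrank(w: WeightMatrix, expr_val: pd.DataFrame, clinical_val: pd.DataFrame) -> float:
    """Log-rank p between predicted B and not-B survival on validation data.

    A degenerate predictor that sends every sample to one group gets
    p = 1 (logged), keeping the trace total while penalizing it.
    """
    for col in ("time", "event"):
        if col not in clinical_val.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    clin = clinical_val.loc[expr_val.columns]
    pred_b = predict_clusters(w, expr_val) == "B"
    if pred_b.all() or (~pred_b).all():
        logger.info("degenerate predictor (single predicted group); log-rank skipped, p=1")
        return 1.0
    res = logrank(
        clin.loc[pred_b, "time"], clin.loc[pred_b, "event"],
        clin.loc[~pred_b, "time"], clin.loc[~pred_b, "event"],
    )
    return res.p_value


def select_point(
    trace: SelectionTrace, criterion: Literal["accuracy", "logrank"]
) -> list[str]:
    """Pick the best iteration's gene set under the given criterion.

    accuracy: maximize; logrank: minimize.  Ties go to the smaller gene
    set, then to the earlier iteration.
    """
    if not trace.iterations:
        raise ValueError("empty selection trace")
    if criterion not in ("accuracy", "logrank"):
        raise ValueError(f"unknown criterion {criterion!r}")
    sign = -1.0 if criterion == "accuracy" else 1.0
    best = min(
        range(len(trace.iterations)),
        key=lambda i: (
            sign * trace.iterations[i].metric,
            len(trace.iterations[i].active_genes),
            i,
        ),
    )
    return list(trace.iterations[best].active_genes)
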