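"""Patient-level vote aggregation and evaluation metrics.

Tile-level class probabilities are re-aggregated per patient either by
range voting (the arithmetic mean of tile probabilities per class, the
default) or by first-past-the-post voting (each tile casts an argmax vote;
the reported probabilities are the vote fractions).  Metrics — ROC-AUC,
accuracy and top-k accuracy — are computed at the patient level, with
nonparametric bootstrap percentile confidence intervals over patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PatientPrediction",
    "MetricResult",
    "aggregate_patient",
    "aggregate_cohort",
    "compute_auc",
    "accuracy",
    "top_k_accuracy",
    "bootstrap_ci",
]


@dataclass
class PatientPrediction:
    patient_id: str
    probabilities: dict
    n_tiles: int
    method: str


@dataclass
class MetricResult:
    metric: str
    value: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_boot: int = 0
    seed: int = 0


def aggregate_patient(
    tile_probs: np.ndarray, method: str = "range_voting"
) -> np.ndarray:
    """Collapse an (n_tiles, n_classes) probability block to one row.

    ``range_voting`` averages tile probabilities per class;
    ``first_past_post`` lets each tile vote for its argmax class (ties to
    the lowest class index) and reports vote fractions.
    """
    probs = np.asarray(tile_probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None]
    if probs.size == 0:
        raise ValueError("patient has no tiles")
    if method == "range_voting":
        return probs.mean(axis=0)
    if method == "first_past_post":
        votes = probs.argmax(axis=1)
        counts = np.bincount(votes, minlength=probs.shape[1])
        return counts / counts.sum()
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_cohort(
    tile_probs: pd.DataFrame,
    class_columns: list,
    method: str = "range_voting",
    patient_column: str = "patient_id",
) -> pd.DataFrame:
    """Aggregate a tile-probability table to one row per patient."""
    out = []
    for patient, block in tile_probs.groupby(patient_column, sort=True):
        agg = aggregate_patient(block[class_columns].to_numpy(), method)
        out.append({patient_column: patient, "n_tiles": len(block),
                    **dict(zip(class_columns, agg))})
    return pd.DataFrame(out)


def compute_auc(scores, labels) -> float:
    """ROC-AUC as Mann-Whitney concordance: P(s+ > s-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy(pred_labels, labels) -> float:
    pred_labels = np.asarray(pred_labels)
    labels = np.asarray(labels)
    return float((pred_labels == labels).mean())


def top_k_accuracy(patient_probs: np.ndarray, label_indices, k: int) -> float:
    """Fraction of patients whose true label is among the k top classes.

    Ties in probability are broken by fixed class order (lower index wins
    the higher rank).
    """
    probs = np.asarray(patient_probs, dtype=float)
    labels = np.asarray(label_indices, dtype=int)
    n_classes = probs.shape[1]
    if not 1 <= k <= n_classes:
        raise ValueError(f"k must lie in [1, {n_classes}]")
    # stable argsort of -prob ranks equal probabilities by class index
    order = np.argsort(-probs, axis=1, kind="stable")
    topk = order[:, :k]
    return float((topk == labels[:, None]).any(axis=1).mean())


def _metric_value(metric: str, scores, labels, k: int | None) -> float:
    if metric == "auc":
        return compute_auc(scores, labels)
    if metric == "accuracy":
        scores = np.asarray(scores)
        if scores.ndim == 2:
            return accuracy(scores.argmax(axis=1), labels)
        return accuracy((np.asarray(scores) >= 0.5).astype(int), labels)
    if metric == "top_k_accuracy":
        return top_k_accuracy(scores, labels, k)
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_ci(
    scores,
    labels,
    metric: str = "auc",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    k: int | None = None,
) -> MetricResult:
    """Percentile bootstrap CI for a patient-level metric.

    Patients are resampled with replacement; resamples on which the metric
    is undefined (e.g. a single-class AUC resample) are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    value = _metric_value(metric, scores, labels, k)

    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if metric == "auc" and len(np.unique(labels[idx])) < 2:
                continue
            break
        stats[b] = _metric_value(metric, scores[idx], labels[idx], k)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return MetricResult(
        metric=metric, value=value, ci_low=float(lo), ci_high=float(hi),
        level=level, n_boot=n_boot, seed=seed,
    )
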