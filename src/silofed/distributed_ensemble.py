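"""Weighted soft-voting ensemble of per-silo models — the distributed model.

Each silo trains a model locally; only the fitted models and their training
scores ever leave the silo.  The distributed model is a convex combination
of the members: weights are the training scores normalized to sum to one
(scores are shifted to be non-negative first, since regression scores are
negative MAE), classification predictions are the weighted average of the
members' class-probability tables, and regression predictions the weighted
average of member outputs.

Aggregation can be simulated *federated* (a central aggregator receives all
scores and computes the weights) or *peer-to-peer* (every node receives all
scores and computes the weights independently); the ensemble mathematics is
identical, and the two modes are asserted equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .learners import CLASSIFICATION, REGRESSION, TrainedLocalModel

AGGREGATION_MODES = ("federated", "peer_to_peer")


@dataclass
class DistributedEnsemble:
    """Ordered per-silo members with normalized soft-voting weights."""

    members: tuple[TrainedLocalModel, ...]
    weights: np.ndarray
    task: str
    class_order: tuple | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self, X)

    def predict(self, X) -> np.ndarray:
        if self.task == REGRESSION:
            return predict_regression(self, X)
        prob = predict_proba(self, X)
        # argmax with lowest-class-code tie-break (class_order is ascending)
        idx = prob.argmax(axis=1)
        return np.asarray(self.class_order)[idx]


def compute_weights(training_scores: Sequence[float]) -> np.ndarray:
    """Score-proportional normalized weights.

    Negative scores (regression uses negative MAE) are shifted by the
    minimum first.  All-equal or degenerate all-zero scores fall back to
    uniform weights.
    """
    scores = np.asarray(list(training_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("at least one training score required")
    if np.any(~np.isfinite(scores)):
        raise ValueError("training scores must be finite")
    if np.min(scores) < 0:
        scores = scores - np.min(scores)
    total = scores.sum()
    if total <= 0 or np.allclose(scores, scores[0]):
        return np.full(scores.size, 1.0 / scores.size)
    return scores / total


def predict_proba(ensemble: DistributedEnsemble, X) -> np.ndarray:
    """Soft vote: ``out[row, class] = sum_i w_i * p_i(row, class)``."""
    if ensemble.task != CLASSIFICATION:
        raise ValueError("predict_proba requires a classification ensemble")
    out = None
    for w, member in zip(ensemble.weights, ensemble.members):
        if tuple(member.class_order) != tuple(ensemble.class_order):
            raise ValueError(
                f"member from silo {member.silo_id} has class order "
                f"{member.class_order}, ensemble expects {ensemble.class_order}"
            )
        p = w * member.predict_proba(X)
        out = p if out is None else out + p
    return out


def predict_regression(ensemble: DistributedEnsemble, X) -> np.ndarray:
    """Weighted average of member predictions."""
    if ensemble.task != REGRESSION:
        raise ValueError("predict_regression requires a regression ensemble")
    out = None
    for w, member in zip(ensemble.weights, ensemble.members):
        p = w * member.predict(X)
        out = p if out is None else out + p
    return out


def aggregate(
    local_models: Sequence[TrainedLocalModel], mode: str = "federated"
) -> DistributedEnsemble:
    """Build the distributed ensemble from per-silo models.

    Inputs are models and scores only — no data tables cross the silo
    boundary.  ``federated``: one aggregator computes the weights from the
    collected scores.  ``peer_to_peer``: every node computes the weights
    independently from the broadcast scores; the computations are asserted
    identical.  The resulting ensemble is the same in both modes.
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}")
    models = list(local_models)
    if not models:
        raise ValueError("at least one local model required")
    task = models[0].spec.task
    class_order = models[0].class_order
    for m in models[1:]:
        if m.spec.task != task:
            raise ValueError("members disagree on task")
        if task == CLASSIFICATION and tuple(m.class_order) != tuple(class_order):
            raise ValueError(
                f"inconsistent class order: silo {m.silo_id} has {m.class_order}"
            )
    scores = [m.training_score for m in models]
    if mode == "federated":
        weights = compute_weights(scores)
    else:
        # every peer computes the weights from the same broadcast scores
        per_node = [compute_weights(scores) for _ in models]
        for w in per_node[1:]:
            assert np.array_equal(w, per_node[0])
        weights = per_node[0]
    return DistributedEnsemble(
        members=tuple(models),
        weights=weights,
        task=task,
        class_order=tuple(class_order) if class_order is not None else None,
    )
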