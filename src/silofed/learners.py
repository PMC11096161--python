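"""The six learner families, local/centralized training, and CV scoring.

Six algorithm families are used in both classification and regression
flavours: decision trees (DT), Gaussian naive Bayes / Bayesian ridge (NB),
logistic regression fitted by stochastic gradient descent / SGD regression
(SGD), k-nearest neighbours (KNN), AdaBoost (ADA), and a multi-layer
perceptron (NN).  Hyperparameters are fixed, documented library defaults —
no tuning — with distance/gradient-based learners wrapped in a standard
scaler.

A model's *training score* (the quantity that later weights it inside the
distributed ensemble) is estimated by repeated stratified cross-validation
(2 repeats x 10 splits by default) with the same headline metric used for
evaluation: prevalence-weighted one-vs-rest AUROC for classification and
negative MAE for regression, so that larger is always better.  The deployed
model is a refit on the full training partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, AdaBoostRegressor
from sklearn.linear_model import BayesianRidge, SGDClassifier, SGDRegressor
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .harmonize import POOLED_SILO_ID

ALGORITHMS = ("SGD", "NN", "KNN", "ADA", "NB", "DT")
CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass(frozen=True)
class LearnerSpec:
    """One of the six algorithm families in one task flavour."""

    algorithm_id: str
    task: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm_id not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; must be one of {ALGORITHMS}"
            )
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass(frozen=True)
class CVSpec:
    """Repeated cross-validation layout (default 2 repeats x 10 splits)."""

    n_repeats: int = 2
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class TrainedLocalModel:
    """A fitted learner plus the silo it came from and its CV training score
    (the basis of its ensemble weight)."""

    spec: LearnerSpec
    silo_id: int
    model: object
    training_score: float
    class_order: tuple | None = None  # global class codes, ascending (classification)

    def __post_init__(self):
        if not np.isfinite(self.training_score):
            raise ValueError("training_score must be finite")

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities aligned to the global ``class_order``; classes
        the fitted model never saw get probability 0."""
        if self.class_order is None:
            raise ValueError("predict_proba requires a classification model")
        raw = self.model.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((raw.shape[0], len(self.class_order)))
        col = {float(c): j for j, c in enumerate(self.class_order)}
        for i, cls in enumerate(_final_estimator(self.model).classes_):
            out[:, col[float(cls)]] = raw[:, i]
        return out

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)))


def _final_estimator(model):
    return model[-1] if isinstance(model, Pipeline) else model


# Fixed hyperparameter table.  Scale-sensitive learners (SGD, NN, KNN) are
# preceded by a standard scaler; tree-based learners are not.  The MLP keeps
# a single 100-unit hidden layer.
def make_learner(spec: LearnerSpec):
    """Instantiate a trainable predictor for the spec; classification
    predictors expose ``predict_proba`` over their fitted classes."""
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    clf = spec.task == CLASSIFICATION
    if spec.algorithm_id == "DT":
        est = (DecisionTreeClassifier if clf else DecisionTreeRegressor)(
            random_state=seed, **hp
        )
        return est
    if spec.algorithm_id == "NB":
        # Gaussian naive Bayes has no regression form; Bayesian ridge is the
        # regression analogue of the Bayesian family.
        est = GaussianNB(**hp) if clf else BayesianRidge(**hp)
        return est
    if spec.algorithm_id == "SGD":
        est = (
            SGDClassifier(loss="log_loss", max_iter=1000, tol=1e-3, random_state=seed, **hp)
            if clf
            else SGDRegressor(max_iter=1000, tol=1e-3, random_state=seed, **hp)
        )
    elif spec.algorithm_id == "KNN":
        est = (KNeighborsClassifier if clf else KNeighborsRegressor)(
            n_neighbors=hp.pop("n_neighbors", 5), **hp
        )
    elif spec.algorithm_id == "ADA":
        est = (AdaBoostClassifier if clf else AdaBoostRegressor)(
            n_estimators=hp.pop("n_estimators", 50), random_state=seed, **hp
        )
        return est
    elif spec.algorithm_id == "NN":
        est = (MLPClassifier if clf else MLPRegressor)(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100,)),
            max_iter=hp.pop("max_iter", 300),
            random_state=seed,
            **hp,
        )
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(spec.algorithm_id)
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def cv_training_score(learner, X, y, cv: CVSpec, task: str) -> float:
    """Mean held-out score over ``n_repeats x n_splits`` folds.

    Classification: prevalence-weighted one-vs-rest AUROC (stratified folds).
    Regression: negative MAE, so that larger is better for both tasks.
    A training fold missing a class indicates a target-prep bug and raises.
    """
    from .evaluation_harness import mae, weighted_ovr_auroc  # deferred: avoids cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training data")
    if task == CLASSIFICATION:
        splitter = RepeatedStratifiedKFold(
            n_splits=cv.n_splits, n_repeats=cv.n_repeats, random_state=cv.seed
        )
        classes = np.unique(y)
    else:
        splitter = RepeatedKFold(
            n_splits=cv.n_splits, n_repeats=cv.n_repeats, random_state=cv.seed
        )
    scores = []
    for train_idx, test_idx in splitter.split(X, y):
        model = clone(learner)
        if task == CLASSIFICATION:
            fold_classes = np.unique(y[train_idx])
            if len(fold_classes) < len(classes):
                missing = sorted(set(classes) - set(fold_classes))
                raise ValueError(
                    f"training fold is missing classes {missing}; target prep "
                    "should have guaranteed fold coverage"
                )
            model.fit(X[train_idx], y[train_idx])
            prob = model.predict_proba(X[test_idx])
            order = _final_estimator(model).classes_
            score = weighted_ovr_auroc(y[test_idx], prob, order)
        else:
            model.fit(X[train_idx], y[train_idx])
            score = -mae(y[test_idx], model.predict(X[test_idx]))
        if np.isfinite(score):
            scores.append(score)
    if not scores:
        raise ValueError("no fold produced a defined score")
    return float(np.mean(scores))


def train_local(
    X,
    y,
    spec: LearnerSpec,
    cv: CVSpec,
    *,
    silo_id: int,
    class_order: Sequence | None = None,
) -> TrainedLocalModel:
    """Train one silo's model: CV-estimate the training score, then refit on
    the whole training partition.  ``class_order`` is the global class list;
    the fitted model must cover it (guaranteed by target prep)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    score = cv_training_score(make_learner(spec), X, y, cv, spec.task)
    model = make_learner(spec)
    model.fit(X, y)
    order = None
    if spec.task == CLASSIFICATION:
        order = tuple(class_order) if class_order is not None else tuple(np.unique(y))
    return TrainedLocalModel(
        spec=spec, silo_id=silo_id, model=model, training_score=score, class_order=order
    )


def train_centralized(
    silo_trains: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: LearnerSpec,
    cv: CVSpec,
    *,
    class_order: Sequence | None = None,
    prep=None,
) -> TrainedLocalModel:
    """Train the centralized baseline on the concatenation of all silos'
    training partitions.  ``prep`` (optional) is a callable ``(X, y) ->
    (X, y)`` applying target repair to the pooled table."""
    if not silo_trains:
        raise ValueError("no silo training partitions")
    X = np.concatenate([np.asarray(Xs, dtype=float) for Xs, _ in silo_trains])
    y = np.concatenate([np.asarray(ys) for _, ys in silo_trains])
    if prep is not None:
        X, y = prep(X, y)
    return train_local(X, y, spec, cv, silo_id=POOLED_SILO_ID, class_order=class_order)
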