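"""Experiment engine: repeated train/test evaluation of local, centralized
and distributed models on per-silo held-out test sets.

For every target x algorithm x repetition, each silo's table is split into
train/test (stratified where possible); the silo trains a local model, the
local models are aggregated into the distributed soft-voting ensemble, and a
centralized model is trained on the pooled training partitions.  All three
model kinds are then evaluated on EVERY silo's held-out test partition, so
each (silo, target, algorithm, repetition) grid point yields three
:class:`MetricRecord`\\ s.

Classification metrics are prevalence-weighted one-vs-rest AUROC (rank /
Mann-Whitney formulation with midrank ties) and prevalence-weighted average
precision (step-wise interpolation); regression metrics are RMSE and MAE.
A metric undefined on a test slice (a single distinct true class) is
recorded as NaN — a flagged gap, never a silent drop or a silent zero.

Two leakage regimes exist.  The default ``per_rep_retrain`` retrains every
model kind inside each repetition, so no test row ever influences training
in its own repetition (asserted by row-id bookkeeping).  ``paper_literal``
builds the distributed and centralized models once per (target, algorithm)
from repetition 0's training partitions and reuses them across repetitions,
which lets them see rows that later repetitions hold out — it reproduces
the literal ordering of the original protocol and is kept for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .distributed_ensemble import aggregate
from .harmonize import SchemaDictionary, SiloDataset
from .learners import (
    ALGORITHMS,
    CLASSIFICATION,
    CVSpec,
    LearnerSpec,
    train_centralized,
    train_local,
)
from .target_prep import TargetPrepConfig, prepare_training_labels

logger = logging.getLogger(__name__)

LEAKAGE_MODES = ("per_rep_retrain", "paper_literal")
MODEL_KINDS = ("local", "centralized", "distributed")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _binary_auroc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank statistic with midrank ties."""
    n1 = int(y_bin.sum())
    n0 = len(y_bin) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[y_bin].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def weighted_ovr_auroc(y_true, prob_table, class_order) -> float:
    """One-vs-rest AUROC per class, averaged with true-class-prevalence
    weights.  Classes absent from ``y_true`` are skipped and the weights
    renormalized.  Undefined (single distinct true class) -> NaN."""
    y_true = np.asarray(y_true)
    prob = np.asarray(prob_table, dtype=float)
    classes = list(class_order)
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        return np.nan
    total = 0.0
    weight = 0.0
    for c in present:
        k = classes.index(c)
        y_bin = y_true == c
        auc = _binary_auroc(y_bin, prob[:, k])
        w = y_bin.mean()
        total += w * auc
        weight += w
    return float(total / weight)


def _average_precision(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise average precision: sum over distinct score thresholds of
    (R_k - R_{k-1}) * P_k, scores descending."""
    n_pos = int(y_bin.sum())
    if n_pos == 0:
        return np.nan
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_bin[order].astype(float)
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, len(y_sorted) + 1)
    # threshold boundaries: last index of each tied block of scores
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[boundary] / n_pred[boundary]
    recall = tp[boundary] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def weighted_auprc(y_true, prob_table, class_order) -> float:
    """Prevalence-weighted one-vs-rest average precision; absent classes are
    skipped with weight renormalization; undefined -> NaN."""
    y_true = np.asarray(y_true)
    prob = np.asarray(prob_table, dtype=float)
    classes = list(class_order)
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        return np.nan
    total = 0.0
    weight = 0.0
    for c in present:
        k = classes.index(c)
        y_bin = y_true == c
        ap = _average_precision(y_bin, prob[:, k])
        w = y_bin.mean()
        total += w * ap
        weight += w
    return float(total / weight)


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("rmse requires equal, non-empty inputs")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("mae requires equal, non-empty inputs")
    return float(np.mean(np.abs(y_true - y_pred)))


# ---------------------------------------------------------------------------
# Experiment configuration and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    n_repetitions: int = 10
    test_fraction: float = 0.2
    cv: CVSpec = CVSpec()
    algorithms: tuple[str, ...] = ALGORITHMS
    targets: tuple[tuple[str, str], ...] = ()
    leakage_mode: str = "per_rep_retrain"
    prep: TargetPrepConfig = TargetPrepConfig()
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.algorithms:
            raise ValueError("at least one algorithm required")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        if self.leakage_mode not in LEAKAGE_MODES:
            raise ValueError(f"leakage_mode must be one of {LEAKAGE_MODES}")


@dataclass
class MetricRecord:
    """One evaluation outcome: one model kind scored on one silo's test set."""

    silo_id: int
    target: str
    algorithm_id: str
    model_kind: str
    repetition: int
    metrics: Mapping[str, float]
    task: str = CLASSIFICATION


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "silo_id": r.silo_id,
            "target": r.target,
            "algorithm_id": r.algorithm_id,
            "model_kind": r.model_kind,
            "repetition": r.repetition,
            "task": r.task,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def enumerate_grid(
    algorithms: Sequence[str], targets: Sequence, silo_ids: Sequence[int]
) -> list[tuple]:
    """All (algorithm, target, silo) comparison-grid cells."""
    return [
        (a, t[0] if isinstance(t, tuple) else t, s)
        for a in algorithms
        for t in targets
        for s in silo_ids
    ]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_silo(
    dataset: SiloDataset,
    target: str,
    test_fraction: float,
    repetition_seed: int,
    task: str = CLASSIFICATION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test partition of one silo, stratified on the target
    where every class allows it (>= 2 members and enough test rows),
    otherwise plain random with a logged warning."""
    df = dataset.table
    n_test = int(round(len(df) * test_fraction))
    if n_test < 1 or n_test >= len(df):
        raise ValueError(
            f"silo {dataset.silo_id}: test fraction {test_fraction} leaves an "
            f"empty partition for {len(df)} rows"
        )
    stratify = None
    if task == CLASSIFICATION:
        y = df[target]
        counts = y.value_counts()
        if counts.min() >= 2 and n_test >= len(counts):
            stratify = y
        else:
            logger.warning(
                "silo %s target %r: cannot stratify (min class count %d, "
                "%d test rows for %d classes); plain random split",
                dataset.silo_id, target, counts.min(), n_test, len(counts),
            )
    train, test = train_test_split(
        df, test_size=n_test, random_state=repetition_seed, stratify=stratify
    )
    return train, test


# ---------------------------------------------------------------------------
# The main loop
# ---------------------------------------------------------------------------


def _substream(master: int, *key: int) -> int:
    """Per-cell reproducible 31-bit seed from the master seed."""
    return int(np.random.default_rng([master, *key]).integers(2**31))


def run_experiment(
    silos: Sequence[SiloDataset],
    schema: SchemaDictionary,
    config: ExperimentConfig,
) -> list[MetricRecord]:
    """Full factorial over targets x algorithms x repetitions x silos."""
    for d in silos:
        d._require_stage("encoded")
    if not config.targets:
        raise ValueError("config.targets is empty; run select_targets first")
    records: list[MetricRecord] = []
    algo_index = {a: i for i, a in enumerate(ALGORITHMS)}
    # globally unique row ids so the leakage audit can compare across silos
    silo_list = [
        SiloDataset(
            d.silo_id,
            d.table.set_axis(
                [d.silo_id * 10**9 + i for i in range(len(d.table))], axis=0
            ),
            d.stage,
        )
        for d in silos
    ]

    for ti, (target, task) in enumerate(config.targets):
        predictors = [c for c in silo_list[0].table.columns if c != target]
        cat_mask = np.array([schema.is_categorical(c) for c in predictors])
        class_order = None
        if task == CLASSIFICATION:
            class_order = tuple(schema.class_codes(target))
        literal_models: dict[str, tuple] = {}  # algorithm -> (ensemble, central)

        for rep in range(config.n_repetitions):
            # fresh split per (target, silo, repetition); shared across algorithms
            splits = []
            for d in silo_list:
                seed = _substream(config.seed, 11, ti, d.silo_id, rep)
                train, test = split_silo(d, target, config.test_fraction, seed, task)
                if len(train) == 0:
                    raise ValueError(
                        f"silo {d.silo_id} has zero training rows for target {target!r}"
                    )
                splits.append((d.silo_id, train, test))

            # target prep per silo (classification only), shared across algorithms
            prepped = []
            for d, (sid, train, test) in zip(silo_list, splits):
                X = train[predictors].to_numpy(dtype=float)
                y = train[target].to_numpy()
                if task == CLASSIFICATION:
                    y = y.astype(int)
                    prep_cfg = TargetPrepConfig(
                        min_class_count=config.prep.min_class_count,
                        smote_neighbors_cap=config.prep.smote_neighbors_cap,
                        seed=_substream(config.seed, 13, ti, sid, rep),
                    )
                    X, y, _rep = prepare_training_labels(
                        X, y, class_order, prep_cfg, categorical_mask=cat_mask, task=task
                    )
                prepped.append((sid, X, y))

            for algo in config.algorithms:
                ai = algo_index[algo]
                locals_: list = []
                for (sid, X, y) in prepped:
                    spec = LearnerSpec(
                        algo, task, seed=_substream(config.seed, 17, ti, ai, sid, rep)
                    )
                    cv = CVSpec(
                        n_repeats=config.cv.n_repeats,
                        n_splits=config.cv.n_splits,
                        seed=_substream(config.seed, 19, ti, ai, sid, rep),
                    )
                    locals_.append(
                        train_local(X, y, spec, cv, silo_id=sid, class_order=class_order)
                    )

                if config.leakage_mode == "paper_literal" and algo in literal_models:
                    ensemble, central = literal_models[algo]
                else:
                    ensemble = aggregate(locals_, mode="federated")
                    pooled_spec = LearnerSpec(
                        algo, task, seed=_substream(config.seed, 23, ti, ai, rep)
                    )
                    pooled_cv = CVSpec(
                        n_repeats=config.cv.n_repeats,
                        n_splits=config.cv.n_splits,
                        seed=_substream(config.seed, 29, ti, ai, rep),
                    )
                    pooled_prep = None
                    if task == CLASSIFICATION:
                        pcfg = TargetPrepConfig(
                            min_class_count=config.prep.min_class_count,
                            smote_neighbors_cap=config.prep.smote_neighbors_cap,
                            seed=_substream(config.seed, 31, ti, ai, rep),
                        )

                        def pooled_prep(X, y, _pcfg=pcfg):
                            X2, y2, _ = prepare_training_labels(
                                X, y.astype(int), class_order, _pcfg,
                                categorical_mask=cat_mask, task=task,
                            )
                            return X2, y2

                    raw_trains = [
                        (t[predictors].to_numpy(dtype=float), t[target].to_numpy())
                        for _, t, _test in splits
                    ]
                    central = train_centralized(
                        raw_trains, pooled_spec, pooled_cv,
                        class_order=class_order, prep=pooled_prep,
                    )
                    if config.leakage_mode == "paper_literal":
                        literal_models[algo] = (ensemble, central)

                # leakage audit: in the default mode no test row of this
                # repetition may appear in any training partition
                if config.leakage_mode == "per_rep_retrain":
                    train_ids = set()
                    for _, train, _test in splits:
                        train_ids.update(train.index.tolist())
                    for _, _train, test in splits:
                        overlap = train_ids & set(test.index.tolist())
                        assert not overlap, f"leakage: rows {sorted(overlap)[:5]}"

                for (sid, _train, test), local_model in zip(splits, locals_):
                    Xt = test[predictors].to_numpy(dtype=float)
                    yt = test[target].to_numpy()
                    for kind, model in (
                        ("local", local_model),
                        ("centralized", central),
                        ("distributed", ensemble),
                    ):
                        metrics = _evaluate(model, Xt, yt, task, class_order)
                        records.append(
                            MetricRecord(
                                silo_id=sid,
                                target=target,
                                algorithm_id=algo,
                                model_kind=kind,
                                repetition=rep,
                                metrics=metrics,
                                task=task,
                            )
                        )
    return records


def _evaluate(model, Xt, yt, task, class_order) -> dict[str, float]:
    if task == CLASSIFICATION:
        yt = yt.astype(int)
        prob = model.predict_proba(Xt)
        return {
            "AUROC": weighted_ovr_auroc(yt, prob, class_order),
            "AUPRC": weighted_auprc(yt, prob, class_order),
        }
    pred = model.predict(Xt)
    return {"RMSE": rmse(yt, pred), "MAE": mae(yt, pred)}
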