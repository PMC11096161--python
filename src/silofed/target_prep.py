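"""Per-training-session repair of target-class pathologies.

Cross-validated training of multi-class models requires every global class
to be present — with enough copies that each fold of a 2x10 stratified CV
contains at least two instances.  Two repairs run per silo, per target,
per training session:

* classes entirely absent from the silo get ``min_class_count`` dummy rows
  whose predictors are the within-silo mean (continuous) / mode (categorical
  code) — this deliberately adds information that is not in the silo, and is
  reported loudly in the :class:`PrepReport`;
* classes with fewer than ``min_class_count`` (default 25) instances are
  raised to exactly that count by SMOTE-style interpolation between
  same-class nearest neighbours on the ordinal-encoded matrix.

Regression targets pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPrepConfig:
    """``min_class_count``: minimum per-class count after repair (default 25,
    which guarantees >= 2 instances of every class in each split of a 2x10
    stratified CV).  ``smote_neighbors_cap``: maximum k for the neighbour
    search."""

    min_class_count: int = 25
    smote_neighbors_cap: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.min_class_count < 2:
            raise ValueError("min_class_count must be >= 2")
        if self.smote_neighbors_cap < 1:
            raise ValueError("smote_neighbors_cap must be >= 1")


@dataclass
class PrepReport:
    """What was repaired for one (silo, target) training session."""

    classes_dummied: list = field(default_factory=list)
    classes_upsampled: list = field(default_factory=list)
    n_rows_before: int = 0
    n_rows_after: int = 0

    @property
    def intervened(self) -> bool:
        return bool(self.classes_dummied or self.classes_upsampled)


def find_missing_classes(y: np.ndarray, global_classes) -> set:
    """Global classes with zero occurrences in ``y``.  A label outside the
    global class list is a schema violation and raises."""
    y = np.asarray(y)
    global_set = set(global_classes)
    observed = set(np.unique(y).tolist())
    alien = observed - global_set
    if alien:
        raise ValueError(f"labels {sorted(alien)} are outside the global class list")
    return global_set - observed


def add_dummy_rows(
    X: np.ndarray,
    y: np.ndarray,
    missing_classes,
    categorical_mask: np.ndarray | None = None,
    n_dummy: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Append ``n_dummy`` identical rows per missing class, predictors set to
    the within-silo column mean (continuous) or mode (categorical code)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("cannot compute within-silo statistics of an empty table")
    if not missing_classes:
        return X, y
    proto = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if categorical_mask is not None and categorical_mask[j]:
            codes, counts = np.unique(col, return_counts=True)
            proto[j] = codes[np.argmax(counts)]  # ties: lowest code
        else:
            proto[j] = col.mean()
    blocks_X, blocks_y = [X], [y]
    for cls in sorted(missing_classes):
        blocks_X.append(np.tile(proto, (n_dummy, 1)))
        blocks_y.append(np.full(n_dummy, cls, dtype=y.dtype))
    return np.concatenate(blocks_X), np.concatenate(blocks_y)


def upsample_rare(
    X: np.ndarray,
    y: np.ndarray,
    config: TargetPrepConfig = TargetPrepConfig(),
    categorical_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raise every class with count ``c < min_class_count`` to exactly
    ``min_class_count`` via SMOTE interpolation.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)`` and
    ``x_nn`` a random one of the ``k = min(cap, c-1)`` nearest same-class
    neighbours (Euclidean on the encoded matrix).  Singleton classes are
    duplicated (interpolation is undefined).  Interpolated categorical codes
    are rounded to the nearest integer code, which stays within the
    coordinate range of the two parents.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    rng = np.random.default_rng(config.seed)
    new_X, new_y = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        c = len(idx)
        if c >= config.min_class_count:
            continue
        need = config.min_class_count - c
        members = X[idx]
        if c == 1:
            synth = np.tile(members[0], (need, 1))
        else:
            k = min(config.smote_neighbors_cap, c - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
            _, neigh = nn.kneighbors(members)  # col 0 is the point itself
            base = rng.integers(c, size=need)
            pick = rng.integers(k, size=need)
            u = rng.random(need)[:, None]
            xi = members[base]
            xn = members[neigh[base, pick + 1]]
            synth = xi + u * (xn - xi)
            if categorical_mask is not None:
                cat = np.asarray(categorical_mask, dtype=bool)
                synth[:, cat] = np.round(synth[:, cat])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    if not new_X:
        return X, y
    return np.concatenate([X] + new_X), np.concatenate([y] + new_y)


def prepare_training_labels(
    X: np.ndarray,
    y: np.ndarray,
    global_classes=None,
    config: TargetPrepConfig = TargetPrepConfig(),
    categorical_mask: np.ndarray | None = None,
    task: str = "classification",
) -> tuple[np.ndarray, np.ndarray, PrepReport]:
    """Full repair: dummy rows for absent classes, then SMOTE for rare ones.

    After this, every global class has count >= ``min_class_count``.  For
    regression targets (or ``global_classes=None``) this is the identity.
    Original rows are preserved unchanged as a prefix of the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    report = PrepReport(n_rows_before=len(X), n_rows_after=len(X))
    if task != "classification" or global_classes is None:
        return X, y, report
    missing = find_missing_classes(y, global_classes)
    counts = {cls: int((y == cls).sum()) for cls in global_classes}
    rare = sorted(
        cls for cls, c in counts.items() if 0 < c < config.min_class_count
    )
    X2, y2 = add_dummy_rows(
        X, y, missing, categorical_mask=categorical_mask, n_dummy=config.min_class_count
    )
    X3, y3 = upsample_rare(X2, y2, config, categorical_mask=categorical_mask)
    report.classes_dummied = sorted(missing)
    report.classes_upsampled = rare
    report.n_rows_after = len(X3)
    if report.intervened:
        logger.info(
            "target prep: dummied classes %s, upsampled classes %s (%d -> %d rows); "
            "dummy/synthetic rows add information not present in the silo",
            report.classes_dummied, report.classes_upsampled,
            report.n_rows_before, report.n_rows_after,
        )
    return X3, y3, report
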