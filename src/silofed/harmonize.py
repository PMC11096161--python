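"""Cross-silo harmonization of raw clinical tables.

Multi-site tabular extracts disagree on how missingness is written
("-1", "missing", an empty field), which columns are usable, and which
categories exist at which site.  This module implements the once-per-dataset
cleaning pipeline: unify missing-value tokens, drop columns that are almost
entirely empty across the pooled sites, impute within site (mean for
continuous columns, a sentinel ``NULLIMP`` category for categorical ones),
build one global ordinal encoding shared by every site, and select target
columns by their pooled null fraction.

Stages are monotone: ``raw -> harmonized -> imputed -> encoded``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel category assigned to missing categorical cells.
NULLIMP = "NULLIMP"

#: Sentinel silo id for models trained on the pooled data.
POOLED_SILO_ID = -1

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

STAGES = ("raw", "harmonized", "imputed", "encoded")


class SchemaMismatchError(ValueError):
    """A table's columns do not agree with the schema."""


class HarmonizeError(ValueError):
    """A harmonization contract was violated."""


class UnknownCategoryError(KeyError):
    """A category was observed that the global ordinal map does not cover.

    This is the central hazard of multi-site training: every class must be
    known to every site before any model is fit, so an unmapped category is
    surfaced loudly with column, category and silo.
    """

    def __init__(self, column: str, category: str, silo_id: int):
        self.column, self.category, self.silo_id = column, category, silo_id
        super().__init__(
            f"category {category!r} in column {column!r} of silo {silo_id} "
            "is not covered by the global ordinal map"
        )


@dataclass(frozen=True)
class SchemaDictionary:
    """Shared data dictionary: column types, missing-token dialect and the
    global ("predefined") category vocabulary and ordinal mapping.

    Parameters
    ----------
    columns
        Ordered ``(name, type)`` pairs; type is ``"continuous"`` or
        ``"categorical"``.
    vocabulary
        Per categorical column, the ordered list of all categories across
        all silos (``NULLIMP`` last once the map is built).
    missing_tokens
        Raw strings that denote a missing value.
    token_sensitive
        Columns in which numeric-looking tokens (e.g. ``"-1"``) also count
        as missing.  ``None`` means every column; an explicit set protects
        columns with legitimate negative numeric values.
    case_insensitive
        Match missing tokens ignoring case (default on).
    ordinal_map
        Per categorical column, ``category -> integer code`` (a bijection
        onto ``0..K-1``).
    """

    columns: tuple[tuple[str, str], ...]
    vocabulary: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    missing_tokens: tuple[str, ...] = ("-1", "missing", "")
    token_sensitive: frozenset[str] | None = None
    case_insensitive: bool = True
    ordinal_map: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        for name, kind in self.columns:
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"column {name!r} has unknown type {kind!r}")
        for col, mapping in self.ordinal_map.items():
            codes = sorted(mapping.values())
            if codes != list(range(len(codes))):
                raise ValueError(f"ordinal codes for {col!r} are not a bijection onto 0..K-1")

    @property
    def column_names(self) -> list[str]:
        return [name for name, _ in self.columns]

    def column_type(self, name: str) -> str:
        for col, kind in self.columns:
            if col == name:
                return kind
        raise KeyError(name)

    def is_categorical(self, name: str) -> bool:
        return self.column_type(name) == CATEGORICAL

    def categorical_columns(self) -> list[str]:
        return [c for c, k in self.columns if k == CATEGORICAL]

    def continuous_columns(self) -> list[str]:
        return [c for c, k in self.columns if k == CONTINUOUS]

    def subset(self, names: Sequence[str]) -> "SchemaDictionary":
        keep = set(names)
        return replace(
            self,
            columns=tuple((c, k) for c, k in self.columns if c in keep),
            vocabulary={c: v for c, v in self.vocabulary.items() if c in keep},
            ordinal_map={c: m for c, m in self.ordinal_map.items() if c in keep},
        )

    def n_classes(self, column: str) -> int:
        return len(self.ordinal_map[column])

    def class_codes(self, column: str) -> list[int]:
        """Global class codes of a categorical column, ascending."""
        return sorted(self.ordinal_map[column].values())

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "columns": [list(c) for c in self.columns],
            "vocabulary": {c: list(v) for c, v in self.vocabulary.items()},
            "missing_tokens": list(self.missing_tokens),
            "token_sensitive": sorted(self.token_sensitive) if self.token_sensitive is not None else None,
            "case_insensitive": self.case_insensitive,
            "ordinal_map": {c: dict(m) for c, m in self.ordinal_map.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SchemaDictionary":
        return cls(
            columns=tuple((str(a), str(b)) for a, b in d["columns"]),
            vocabulary={c: tuple(v) for c, v in d.get("vocabulary", {}).items()},
            missing_tokens=tuple(d.get("missing_tokens", ("-1", "missing", ""))),
            token_sensitive=(
                frozenset(d["token_sensitive"]) if d.get("token_sensitive") is not None else None
            ),
            case_insensitive=bool(d.get("case_insensitive", True)),
            ordinal_map={c: {k: int(v) for k, v in m.items()} for c, m in d.get("ordinal_map", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SchemaDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SiloDataset:
    """One institution's table plus its silo identifier and pipeline stage."""

    silo_id: int
    table: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise HarmonizeError(
                f"silo {self.silo_id}: operation requires stage in {allowed}, got {self.stage!r}"
            )

    def copy(self) -> "SiloDataset":
        return SiloDataset(self.silo_id, self.table.copy(), self.stage)


@dataclass(frozen=True)
class HarmonizeConfig:
    """Thresholds of the cleaning pipeline.

    ``sparse_drop_fraction``: a column is dropped when its pooled missing
    fraction is strictly greater than this (default 0.90).
    ``target_null_fraction``: a column becomes a modelling target when its
    pooled missing fraction is strictly below this (default 0.50).
    """

    sparse_drop_fraction: float = 0.90
    target_null_fraction: float = 0.50

    def __post_init__(self):
        for name in ("sparse_drop_fraction", "target_null_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def unify_missing(dataset: SiloDataset, schema: SchemaDictionary) -> SiloDataset:
    """Replace every raw missing token with the single unified marker (NaN).

    Cells are compared after trimming surrounding whitespace, optionally
    case-insensitively.  In columns not flagged token-sensitive, tokens that
    parse as numbers (e.g. ``"-1"``) are NOT treated as missing in continuous
    columns, so legitimate negative values survive.  Idempotent.
    """
    dataset._require_stage("raw", "harmonized")
    unknown = [c for c in dataset.table.columns if c not in schema.column_names]
    if unknown:
        raise SchemaMismatchError(
            f"silo {dataset.silo_id}: columns {unknown} not in schema"
        )

    tokens = set(schema.missing_tokens) | {""}
    if schema.case_insensitive:
        tokens = {t.lower() for t in tokens}
    numeric_tokens = {t for t in tokens if _is_number(t)}

    out = dataset.table.copy()
    for col in out.columns:
        sensitive = schema.token_sensitive is None or col in schema.token_sensitive
        col_tokens = tokens
        if not sensitive and schema.column_type(col) == CONTINUOUS:
            col_tokens = tokens - numeric_tokens
        ser = out[col]
        mask = ser.isna().to_numpy()
        vals = ser.astype("object").to_numpy()
        for i, v in enumerate(vals):
            if mask[i]:
                continue
            s = str(v).strip()
            if schema.case_insensitive:
                s = s.lower()
            if s in col_tokens:
                mask[i] = True
        vals[mask] = np.nan
        out[col] = vals
    return SiloDataset(dataset.silo_id, out, "harmonized")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def pooled_missing_fraction(datasets: Sequence[SiloDataset]) -> pd.Series:
    """Missing fraction per column over the concatenation of all silos."""
    if not datasets:
        raise HarmonizeError("no datasets")
    total = sum(len(d.table) for d in datasets)
    if total == 0:
        raise HarmonizeError("zero total rows across silos")
    counts = pd.concat([d.table.isna().sum() for d in datasets], axis=1).sum(axis=1)
    return counts / total


def drop_sparse_columns(
    datasets: Sequence[SiloDataset], config: HarmonizeConfig = HarmonizeConfig()
) -> tuple[list[SiloDataset], list[str], list[str]]:
    """Drop columns whose pooled missing fraction strictly exceeds the
    sparse threshold; returns (datasets, retained, dropped)."""
    for d in datasets:
        d._require_stage("harmonized")
    cols = list(datasets[0].table.columns)
    for d in datasets[1:]:
        if list(d.table.columns) != cols:
            raise SchemaMismatchError("silos have differing column sets")
    frac = pooled_missing_fraction(datasets)
    dropped = [c for c in cols if frac[c] > config.sparse_drop_fraction]
    retained = [c for c in cols if c not in dropped]
    if dropped:
        logger.info("dropping %d sparse columns (>%.0f%% pooled missing): %s",
                    len(dropped), 100 * config.sparse_drop_fraction, dropped)
    out = [SiloDataset(d.silo_id, d.table[retained].copy(), d.stage) for d in datasets]
    return out, retained, dropped


def impute(
    dataset: SiloDataset,
    schema: SchemaDictionary,
    fallback_means: Mapping[str, float] | None = None,
) -> SiloDataset:
    """Within-site imputation: column mean for continuous cells, the
    ``NULLIMP`` category for categorical cells.

    A continuous column that is entirely missing within this silo falls back
    to the cross-silo mean supplied by the caller (with a logged warning);
    without a fallback this is an error.  Idempotent on imputed data.
    """
    if dataset.stage == "imputed":
        return dataset.copy()
    dataset._require_stage("harmonized")
    out = dataset.table.copy()
    for col in out.columns:
        missing = out[col].isna()
        if schema.column_type(col) == CATEGORICAL:
            vals = out[col].astype("object").to_numpy()
            vals[missing.to_numpy()] = NULLIMP
            out[col] = vals
        else:
            numeric = pd.to_numeric(out[col], errors="coerce")
            if numeric[~missing].isna().any():
                bad = out[col][~missing & numeric.isna()].iloc[0]
                raise HarmonizeError(
                    f"silo {dataset.silo_id}: non-numeric value {bad!r} in continuous column {col!r}"
                )
            if missing.all():
                if fallback_means is None or col not in fallback_means:
                    raise HarmonizeError(
                        f"silo {dataset.silo_id}: column {col!r} entirely missing and no fallback mean supplied"
                    )
                fill = float(fallback_means[col])
                logger.warning(
                    "silo %s: column %r entirely missing within site; using cross-silo mean %.6g",
                    dataset.silo_id, col, fill,
                )
            else:
                fill = float(numeric[~missing].mean())
            out[col] = numeric.fillna(fill).astype(float)
    return SiloDataset(dataset.silo_id, out, "imputed")


def build_ordinal_map(
    datasets: Sequence[SiloDataset], schema: SchemaDictionary
) -> SchemaDictionary:
    """Build the global ordinal encoding shared by every silo.

    Per categorical column the vocabulary is the lexicographically sorted
    union of the categories observed in ALL silos (plus any predeclared in
    the schema), with ``NULLIMP`` appended last; codes run ``0..K-1`` in
    vocabulary order and the same map applies to each silo and to the pooled
    table.
    """
    for d in datasets:
        d._require_stage("imputed", "encoded")
    vocabulary: dict[str, tuple[str, ...]] = {}
    ordinal_map: dict[str, dict[str, int]] = {}
    present = set(datasets[0].table.columns) if datasets else set()
    for col in schema.categorical_columns():
        if datasets and col not in present:
            continue
        cats: set[str] = set(schema.vocabulary.get(col, ()))
        for d in datasets:
            cats.update(str(v) for v in d.table[col].unique())
        cats.discard(NULLIMP)
        ordered = sorted(cats) + [NULLIMP]
        vocabulary[col] = tuple(ordered)
        ordinal_map[col] = {c: i for i, c in enumerate(ordered)}
    return replace(schema, vocabulary=vocabulary, ordinal_map=ordinal_map)


def encode(dataset: SiloDataset, schema: SchemaDictionary) -> SiloDataset:
    """Apply the global ordinal map: categorical cells become integer codes,
    continuous cells become floats.  An unmapped category raises
    :class:`UnknownCategoryError` naming column, category and silo."""
    dataset._require_stage("imputed")
    if not schema.ordinal_map:
        raise HarmonizeError("schema has no ordinal map; run build_ordinal_map first")
    out = dataset.table.copy()
    for col in out.columns:
        if schema.column_type(col) == CATEGORICAL:
            mapping = schema.ordinal_map[col]
            codes = np.empty(len(out), dtype=float)
            for i, v in enumerate(out[col].astype(str).to_numpy()):
                try:
                    codes[i] = mapping[v]
                except KeyError:
                    raise UnknownCategoryError(col, v, dataset.silo_id) from None
            out[col] = codes
        else:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
    return SiloDataset(dataset.silo_id, out, "encoded")


def select_targets(
    datasets: Sequence[SiloDataset],
    schema: SchemaDictionary,
    config: HarmonizeConfig = HarmonizeConfig(),
) -> list[tuple[str, str]]:
    """Select modelling targets: columns whose pooled missing fraction on the
    harmonized (pre-imputation) data is strictly below the null threshold.
    Categorical columns become classification tasks, continuous columns
    regression tasks."""
    for d in datasets:
        d._require_stage("harmonized")
    frac = pooled_missing_fraction(datasets)
    targets: list[tuple[str, str]] = []
    for col in datasets[0].table.columns:
        if frac[col] < config.target_null_fraction:
            task = "classification" if schema.is_categorical(col) else "regression"
            targets.append((col, task))
    if not targets:
        logger.warning("no columns satisfy the target null-fraction filter")
    return targets


def harmonize_all(
    datasets: Sequence[SiloDataset],
    schema: SchemaDictionary,
    config: HarmonizeConfig = HarmonizeConfig(),
) -> tuple[list[SiloDataset], SchemaDictionary, list[tuple[str, str]]]:
    """Run the full pipeline on raw silos.

    Returns (encoded silos, schema with ordinal map restricted to retained
    columns, selected targets).
    """
    unified = [unify_missing(d, schema) for d in datasets]
    unified, retained, _dropped = drop_sparse_columns(unified, config)
    targets = select_targets(unified, schema.subset(retained), config)
    pooled = pooled_cross_silo_means(unified, schema)
    imputed = [impute(d, schema, fallback_means=pooled) for d in unified]
    mapped = build_ordinal_map(imputed, schema.subset(retained))
    encoded = [encode(d, mapped) for d in imputed]
    return encoded, mapped, targets


def pooled_cross_silo_means(
    datasets: Sequence[SiloDataset], schema: SchemaDictionary
) -> dict[str, float]:
    """Cross-silo means of continuous columns, the fallback for columns that
    are entirely missing within a single site."""
    means: dict[str, float] = {}
    for col in datasets[0].table.columns:
        if schema.column_type(col) == CONTINUOUS:
            pooled = pd.concat([pd.to_numeric(d.table[col], errors="coerce") for d in datasets])
            if pooled.notna().any():
                means[col] = float(pooled.mean())
    return means
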