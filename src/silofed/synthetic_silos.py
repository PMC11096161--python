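"""Synthetic multi-silo obstetrics-like data generator.

Real multi-hospital delivery records cannot be redistributed, so every
downstream stage is exercised on generated tables that reproduce the
*statistical structure* the analysis has to survive: nine silos of very
unequal size, ~35 mixed categorical/continuous columns, heterogeneous
per-silo missingness (some columns >90% empty), inconsistent raw missing
tokens ("-1", "missing", blank), per-silo covariate shift, rare target
classes, and classes entirely absent from some silos.

The generator uses independent silo-shifted marginals (Gaussian for
continuous columns, multinomial for categorical ones) plus an explicit
latent signal layer linking a configurable subset of predictors to each
designated target, so that models can beat chance and the
distributed-vs-centralized comparison is non-trivial.  Silo shift perturbs
continuous means and categorical log-odds by ``shift_strength x column SD``;
``shift_strength = 0`` yields IID silos for degeneracy tests.

Generation is a pure function of the config (master seed streamed into
per-silo, per-column substreams, so editing one silo's profile does not
perturb the others).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import (
    CATEGORICAL,
    CONTINUOUS,
    NULLIMP,
    SchemaDictionary,
    SiloDataset,
)

#: Per-silo row counts of the nine-hospital study (total 80,874).
STUDY_SILO_SIZES = (8039, 8566, 4989, 2364, 18177, 12002, 8258, 6693, 11786)

DEFAULT_TOKEN_DIALECT = ("-1", "missing", "")


@dataclass(frozen=True)
class SiloProfile:
    """Generator parameters of one silo."""

    silo_id: int
    n_rows: int
    shift_strength: float
    missing_rate_by_column: Mapping[str, float]
    token_dialect: tuple[str, ...] = DEFAULT_TOKEN_DIALECT

    def __post_init__(self):
        if self.n_rows < 1:
            raise ValueError(f"silo {self.silo_id}: n_rows must be >= 1, got {self.n_rows}")
        if self.shift_strength < 0:
            raise ValueError("shift_strength must be non-negative")
        for col, r in self.missing_rate_by_column.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {col!r} must be in [0,1], got {r}")
        if not self.token_dialect:
            raise ValueError("token_dialect must be non-empty")


@dataclass(frozen=True)
class SignalSpec:
    """Latent signal linking predictors to one designated target column."""

    predictors: tuple[str, ...]
    strength: float = 1.5
    #: fraction of target variance explained (continuous targets only)
    r_squared: float = 0.5


@dataclass(frozen=True)
class ColumnSpec:
    """Marginal description of one schema column.

    Continuous columns carry ``mean``/``sd``; categorical ones carry the
    number of levels and the frequency of the most common level, the rest of
    the mass decaying geometrically.
    """

    name: str
    kind: str
    mean: float = 0.0
    sd: float = 1.0
    n_levels: int = 0
    top_freq: float = 0.0
    base_missing: float = 0.05
    is_target: bool = False


# Column catalog mirroring the pooled summaries of a nine-hospital obstetrics
# dataset: name, type, marginal parameters, pooled missing rate, and whether
# the column passes the <50%-null target filter.  Columns with base_missing
# > 0.9 exercise the sparse-column drop; columns in [0.5, 0.9) are retained
# as predictors but excluded from the target list.
_CAT = CATEGORICAL
_CON = CONTINUOUS
COLUMN_CATALOG: tuple[ColumnSpec, ...] = (
    ColumnSpec("actual_type_of_delivery", _CAT, n_levels=11, top_freq=0.529, base_missing=0.05, is_target=True),
    ColumnSpec("bishop_score", _CAT, n_levels=16, top_freq=0.953, base_missing=0.95),
    ColumnSpec("blood_group", _CAT, n_levels=14, top_freq=0.405, base_missing=0.10, is_target=True),
    ColumnSpec("body_mass_index", _CON, mean=25.1, sd=7.0, base_missing=0.10, is_target=True),
    ColumnSpec("cervical_consistency", _CAT, n_levels=4, top_freq=0.965, base_missing=0.96),
    ColumnSpec("cervical_position", _CAT, n_levels=4, top_freq=0.966, base_missing=0.96),
    ColumnSpec("delivery_type", _CAT, n_levels=8, top_freq=0.513, base_missing=0.05, is_target=True),
    ColumnSpec("dilatation", _CAT, n_levels=5, top_freq=0.965, base_missing=0.96),
    ColumnSpec("effacement", _CAT, n_levels=5, top_freq=0.965, base_missing=0.96),
    ColumnSpec("fetal_station", _CAT, n_levels=5, top_freq=0.966, base_missing=0.96),
    ColumnSpec("followed_physician", _CAT, n_levels=4, top_freq=0.979, base_missing=0.05, is_target=True),
    ColumnSpec("followed_physician_hospital_delivery", _CAT, n_levels=2, top_freq=0.690, base_missing=0.05, is_target=True),
    ColumnSpec("followed_physician_primary_care", _CAT, n_levels=2, top_freq=0.676, base_missing=0.05, is_target=True),
    ColumnSpec("followed_physician_private_clinic", _CAT, n_levels=2, top_freq=0.758, base_missing=0.60),
    ColumnSpec("gestational_diabetes", _CAT, n_levels=2, top_freq=0.895, base_missing=0.60),
    ColumnSpec("induced_delivery", _CAT, n_levels=2, top_freq=0.925, base_missing=0.65),
    ColumnSpec("mother_age", _CON, mean=31.1, sd=5.6, base_missing=0.05, is_target=True),
    ColumnSpec("nr_deliveries_forceps", _CAT, n_levels=5, top_freq=0.826, base_missing=0.70),
    ColumnSpec("nr_deliveries_no_assistance", _CAT, n_levels=12, top_freq=0.603, base_missing=0.70),
    ColumnSpec("nr_deliveries_vacuum", _CAT, n_levels=5, top_freq=0.774, base_missing=0.70),
    ColumnSpec("nr_of_c_sections", _CAT, n_levels=6, top_freq=0.746, base_missing=0.70),
    ColumnSpec("nr_of_pregnancies", _CAT, n_levels=19, top_freq=0.421, base_missing=0.10, is_target=True),
    ColumnSpec("nr_of_born_babies", _CAT, n_levels=12, top_freq=0.388, base_missing=0.10, is_target=True),
    ColumnSpec("nr_of_consultations", _CON, mean=8.4, sd=5.1, base_missing=0.15, is_target=True),
    ColumnSpec("pelvis_adequacy", _CAT, n_levels=4, top_freq=0.826, base_missing=0.60),
    ColumnSpec("position_admission", _CAT, n_levels=7, top_freq=0.731, base_missing=0.10, is_target=True),
    ColumnSpec("position_on_delivery", _CAT, n_levels=5, top_freq=0.939, base_missing=0.05, is_target=True),
    ColumnSpec("pregnancy_type", _CAT, n_levels=7, top_freq=0.854, base_missing=0.05, is_target=True),
    ColumnSpec("robson_group", _CAT, n_levels=11, top_freq=0.244, base_missing=0.10, is_target=True),
    ColumnSpec("rupture_amniotic_pocket", _CAT, n_levels=2, top_freq=0.885, base_missing=0.60),
    ColumnSpec("smoker", _CAT, n_levels=2, top_freq=0.881, base_missing=0.55),
    ColumnSpec("spontaneous_delivery", _CAT, n_levels=2, top_freq=0.649, base_missing=0.05, is_target=True),
    ColumnSpec("weeks_on_admission", _CON, mean=38.7, sd=2.2, base_missing=0.05, is_target=True),
    ColumnSpec("weeks_on_delivery", _CON, mean=38.9, sd=2.0, base_missing=0.05, is_target=True),
    ColumnSpec("weight_on_admission", _CON, mean=78.8, sd=14.5, base_missing=0.55),
    ColumnSpec("weight_start_pregnancy", _CON, mean=66.0, sd=14.1, base_missing=0.15, is_target=True),
)

_CATALOG_BY_NAME = {c.name: c for c in COLUMN_CATALOG}

#: Default latent signal layer.  The signal targets are a stand-in making the
#: learning problem non-trivial, not a claim about obstetric physiology.
DEFAULT_SIGNALS: dict[str, SignalSpec] = {
    "spontaneous_delivery": SignalSpec(("mother_age", "weeks_on_admission", "body_mass_index"), strength=1.8),
    "delivery_type": SignalSpec(("body_mass_index", "mother_age"), strength=1.2),
    "robson_group": SignalSpec(("mother_age", "nr_of_consultations"), strength=1.0),
    "weeks_on_delivery": SignalSpec(("weeks_on_admission", "nr_of_consultations"), r_squared=0.6),
    "weight_start_pregnancy": SignalSpec(("body_mass_index",), r_squared=0.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic multi-silo study."""

    profiles: tuple[SiloProfile, ...]
    schema: SchemaDictionary
    rare_class_spec: Mapping[tuple[str, str], int] = field(default_factory=dict)
    absent_class_spec: Mapping[tuple[str, str], frozenset[int]] = field(default_factory=dict)
    signal_spec: Mapping[str, SignalSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        ids = [p.silo_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("silo ids must be unique")
        for key, count in self.rare_class_spec.items():
            if count < 1:
                raise ValueError(f"rare-class count for {key} must be >= 1")
        all_ids = set(ids)
        for (col, cls), silos in self.absent_class_spec.items():
            if not set(silos) < all_ids:
                raise ValueError(
                    f"absent-class silos for ({col!r}, {cls!r}) must be a strict "
                    "subset of all silos (the class must exist somewhere)"
                )

    @property
    def silo_ids(self) -> list[int]:
        return [p.silo_id for p in self.profiles]


# ---------------------------------------------------------------------------
# Default configuration emulating the nine-hospital study
# ---------------------------------------------------------------------------


def _level_names(k: int) -> list[str]:
    return [f"v{i:02d}" for i in range(k)]


def _level_probs(spec: ColumnSpec) -> np.ndarray:
    """Most frequent level gets ``top_freq``; the rest decays geometrically."""
    k = spec.n_levels
    if k == 1:
        return np.ones(1)
    rest = 0.7 ** np.arange(k - 1)
    rest = rest / rest.sum() * (1.0 - spec.top_freq)
    return np.concatenate([[spec.top_freq], rest])


def default_obstetrics_config(
    scale: float,
    seed: int = 0,
    shift_strength: float = 0.3,
) -> GeneratorConfig:
    """Config emulating the nine-hospital obstetrics study at a given scale.

    ``scale = 1`` reproduces the study's silo sizes (total 80,874 rows);
    tests and desk-scale runs use ``scale`` around 0.02.  Raises if any silo
    would round to zero rows.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    sizes = [round(scale * n) for n in STUDY_SILO_SIZES]
    if any(n < 1 for n in sizes):
        raise ValueError(
            f"scale={scale} rounds the smallest silo to zero rows; "
            f"minimum workable scale is {0.5 / min(STUDY_SILO_SIZES):.2g}"
        )

    rng = np.random.default_rng([seed, 151])
    profiles = []
    for i, n in enumerate(sizes, start=1):
        # heterogeneous per-silo missingness around each column's pooled rate
        rates = {}
        for spec in COLUMN_CATALOG:
            jitter = float(rng.uniform(0.8, 1.2))
            rate = spec.base_missing * jitter
            if spec.base_missing > 0.9:
                rate = max(rate, 0.92)  # keep sparse columns above the drop line
            elif spec.is_target:
                rate = min(rate, 0.40)  # keep targets safely under the null filter
            else:
                rate = min(max(rate, 0.52), 0.88)
            rates[spec.name] = min(rate, 0.99)
        profiles.append(
            SiloProfile(
                silo_id=i,
                n_rows=n,
                shift_strength=shift_strength,
                missing_rate_by_column=rates,
                token_dialect=DEFAULT_TOKEN_DIALECT,
            )
        )

    schema = SchemaDictionary(
        columns=tuple((c.name, c.kind) for c in COLUMN_CATALOG),
        vocabulary={
            c.name: tuple(_level_names(c.n_levels)) + (NULLIMP,)
            for c in COLUMN_CATALOG
            if c.kind == CATEGORICAL
        },
    )

    total = sum(sizes)
    rare_count = max(1, min(15, total - 1))
    return GeneratorConfig(
        profiles=tuple(profiles),
        schema=schema,
        # a globally rare class (< 25 instances) to exercise SMOTE repair
        rare_class_spec={("robson_group", "v10"): rare_count},
        # a class withheld from one silo to exercise dummy-row repair
        absent_class_spec={("delivery_type", "v07"): frozenset({3})},
        signal_spec=dict(DEFAULT_SIGNALS),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _rng(config: GeneratorConfig, *key) -> np.random.Generator:
    ints = [config.seed] + [k if isinstance(k, int) else _str_seed(k) for k in key]
    return np.random.default_rng(ints)


def _str_seed(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def _column_index(name: str) -> int:
    return list(_CATALOG_BY_NAME).index(name)


def _shift(config, profile, spec) -> float:
    """Per-(silo, column) mean shift in SD units, scaled by shift_strength."""
    z = float(_rng(config, "shift", profile.silo_id, _column_index(spec.name)).standard_normal())
    return profile.shift_strength * z


def _silo_category_probs(config, profile, spec) -> np.ndarray:
    """Silo-shifted class probabilities with withheld classes removed."""
    base = _level_probs(spec)
    logits = np.log(np.maximum(base, 1e-12))
    g = _rng(config, "catshift", profile.silo_id, _column_index(spec.name)).standard_normal(len(base))
    logits = logits + profile.shift_strength * g
    p = np.exp(logits - logits.max())
    p /= p.sum()
    levels = _level_names(spec.n_levels)
    for (col, cls), silos in config.absent_class_spec.items():
        if col == spec.name and profile.silo_id in silos and cls in levels:
            p[levels.index(cls)] = 0.0
    s = p.sum()
    if s <= 0:
        raise ValueError(f"all classes of {spec.name!r} withheld from silo {profile.silo_id}")
    return p / s


def generate(config: GeneratorConfig) -> list[SiloDataset]:
    """Generate one raw table per silo profile.

    Deterministic: the same config (including seed) yields byte-identical
    tables.  Missing cells carry a raw token drawn uniformly from the silo's
    dialect; all values are strings, as read from a CSV extract.
    """
    specs = [
        _CATALOG_BY_NAME.get(name, None) or _fallback_spec(name, kind)
        for name, kind in config.schema.columns
    ]
    total_rows = sum(p.n_rows for p in config.profiles)
    for (col, cls), count in config.rare_class_spec.items():
        if count > total_rows:
            raise ValueError(
                f"rare-class spec for ({col!r}, {cls!r}) requests {count} rows "
                f"but only {total_rows} exist"
            )

    signal = dict(config.signal_spec)
    values: dict[int, dict[str, np.ndarray]] = {}

    for profile in config.profiles:
        n = profile.n_rows
        cols: dict[str, np.ndarray] = {}
        # pass 1: continuous, non-signal columns
        for spec in specs:
            if spec.kind == CONTINUOUS and spec.name not in signal:
                r = _rng(config, "col", profile.silo_id, _column_index(spec.name))
                delta = _shift(config, profile, spec) * spec.sd
                cols[spec.name] = spec.mean + delta + spec.sd * r.standard_normal(n)
        # pass 2: signal-driven continuous columns
        for spec in specs:
            if spec.kind == CONTINUOUS and spec.name in signal:
                sig = signal[spec.name]
                score = _signal_score(cols, sig, spec.name)
                r = _rng(config, "col", profile.silo_id, _column_index(spec.name))
                delta = _shift(config, profile, spec) * spec.sd
                noise = r.standard_normal(n)
                r2 = sig.r_squared
                cols[spec.name] = (
                    spec.mean + delta
                    + spec.sd * (math.sqrt(r2) * score + math.sqrt(1.0 - r2) * noise)
                )
        # pass 3: categorical columns
        for spec in specs:
            if spec.kind != CATEGORICAL:
                continue
            r = _rng(config, "col", profile.silo_id, _column_index(spec.name))
            p = _silo_category_probs(config, profile, spec)
            levels = np.array(_level_names(spec.n_levels), dtype=object)
            if spec.name in signal:
                sig = signal[spec.name]
                score = _signal_score(cols, sig, spec.name)
                # class-specific tilt: low classes favoured at low scores
                w = np.linspace(-1.0, 1.0, spec.n_levels)
                logits = np.log(np.maximum(p, 1e-300))[None, :] + sig.strength * score[:, None] * w[None, :]
                logits[:, p == 0] = -np.inf
                prob = np.exp(logits - logits.max(axis=1, keepdims=True))
                prob /= prob.sum(axis=1, keepdims=True)
                u = r.random(n)
                idx = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)
            else:
                idx = r.choice(spec.n_levels, size=n, p=p)
            cols[spec.name] = levels[idx]
        values[profile.silo_id] = cols

    _enforce_rare_classes(config, specs, values)
    _enforce_class_coverage(config, specs, values)

    datasets = []
    for profile in config.profiles:
        cols = values[profile.silo_id]
        table = _stringify_and_mask(config, profile, specs, cols)
        datasets.append(SiloDataset(profile.silo_id, table, "raw"))
    return datasets


def _fallback_spec(name: str, kind: str) -> ColumnSpec:
    if kind == CONTINUOUS:
        return ColumnSpec(name, kind, mean=0.0, sd=1.0)
    return ColumnSpec(name, kind, n_levels=2, top_freq=0.7)


def _signal_score(cols: dict[str, np.ndarray], sig: SignalSpec, target: str) -> np.ndarray:
    missing = [p for p in sig.predictors if p not in cols]
    if missing:
        raise ValueError(f"signal target {target!r} references ungenerated predictors {missing}")
    parts = []
    for p in sig.predictors:
        spec = _CATALOG_BY_NAME[p]
        parts.append((cols[p] - spec.mean) / spec.sd)
    score = np.mean(parts, axis=0)
    return score * math.sqrt(len(parts))  # unit variance if predictors independent


def _enforce_rare_classes(config, specs, values) -> None:
    """Force each (column, class) in the rare-class spec to exactly its
    intended global count, respecting withheld-class silos."""
    for (col, cls), target_count in config.rare_class_spec.items():
        withheld = config.absent_class_spec.get((col, cls), frozenset())
        r = _rng(config, "rare", _column_index(col))
        spec = _CATALOG_BY_NAME[col]
        modal = _level_names(spec.n_levels)[0]
        slots = []  # (silo_id, row) positions where the class may live
        current = []  # positions currently holding the class
        for profile in config.profiles:
            arr = values[profile.silo_id][col]
            for i in np.flatnonzero(arr == cls):
                current.append((profile.silo_id, int(i)))
            if profile.silo_id not in withheld:
                slots.extend((profile.silo_id, int(i)) for i in range(len(arr)))
        if len(current) > target_count:
            demote = r.choice(len(current), size=len(current) - target_count, replace=False)
            for j in demote:
                sid, i = current[j]
                values[sid][col][i] = modal
        elif len(current) < target_count:
            free = [s for s in slots if values[s[0]][col][s[1]] != cls]
            promote = r.choice(len(free), size=target_count - len(current), replace=False)
            for j in promote:
                sid, i = free[j]
                values[sid][col][i] = cls


def _enforce_class_coverage(config, specs, values) -> None:
    """Guarantee every vocabulary class occurs at least once globally (in a
    silo not withholding it)."""
    for spec in specs:
        if spec.kind != CATEGORICAL:
            continue
        levels = _level_names(spec.n_levels)
        pooled = np.concatenate([values[p.silo_id][spec.name] for p in config.profiles])
        present = set(pooled.tolist())
        for cls in levels:
            if cls in present:
                continue
            if (spec.name, cls) in config.rare_class_spec:
                continue  # handled above
            withheld = config.absent_class_spec.get((spec.name, cls), frozenset())
            hosts = [p for p in config.profiles if p.silo_id not in withheld]
            r = _rng(config, "cover", _column_index(spec.name), levels.index(cls))
            host = hosts[int(r.integers(len(hosts)))]
            row = int(r.integers(host.n_rows))
            values[host.silo_id][spec.name][row] = cls


def _stringify_and_mask(config, profile, specs, cols) -> pd.DataFrame:
    n = profile.n_rows
    out = {}
    for spec in specs:
        vals = cols[spec.name]
        if spec.kind == CONTINUOUS:
            strs = np.array([format(v, ".3f") for v in vals], dtype=object)
        else:
            strs = vals.astype(object).copy()
        rate = profile.missing_rate_by_column.get(spec.name, 0.0)
        if rate > 0:
            r = _rng(config, "miss", profile.silo_id, _column_index(spec.name))
            mask = r.random(n) < rate
            tokens = np.array(profile.token_dialect, dtype=object)
            strs[mask] = tokens[r.integers(len(tokens), size=int(mask.sum()))]
        out[spec.name] = strs
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_silos(
    datasets: Sequence[SiloDataset],
    directory,
    schema: SchemaDictionary | None = None,
) -> list[Path]:
    """Write one CSV per silo (raw tokens verbatim, including empty fields)
    plus a companion ``schema.json``.  Returns the written paths."""
    if not datasets:
        raise ValueError("no datasets to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for d in datasets:
        path = directory / f"silo_{d.silo_id}.csv"
        d.table.to_csv(path, index=False, lineterminator="\n")
        paths.append(path)
    if schema is not None:
        spath = directory / "schema.json"
        schema.to_json(spath)
        paths.append(spath)
    return paths
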