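"""Statistical comparison of distributed vs centralized vs local models.

Per (algorithm, target, silo) grid cell, the repetition-level values of a
driver metric (AUROC for classification, MAE for regression) are compared
with independent two-sample t-tests at alpha = 0.05: the distributed model
against the centralized model, and against the silo's local model.  A
non-significant difference is *equal*; otherwise the mean decides *better*
or *worse* under the metric's orientation.  The cells are tallied into a
3x3 relation contingency per algorithm (rows: vs centralized, columns:
vs local), and an aggregate summary reports per-metric means with 95%
normal-approximation confidence intervals and pooled t-tests.

The default t-test is the pooled-variance Student's t (Welch is available
by flag).  No multiple-testing correction is applied across the >1000
cells, matching the protocol being reproduced; an optional Holm adjustment
is exposed but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation_harness import MetricRecord, records_to_frame

RELATIONS = ("better", "equal", "worse")

DEFAULT_ORIENTATION = {
    "AUROC": "higher_better",
    "AUPRC": "higher_better",
    "RMSE": "lower_better",
    "MAE": "lower_better",
}

DEFAULT_DRIVER = {"classification": "AUROC", "regression": "MAE"}


@dataclass(frozen=True)
class ComparisonConfig:
    alpha: float = 0.05
    equal_variance: bool = True
    orientation: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    driver_metric: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_DRIVER))
    holm: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ComparisonCell:
    """One grid cell's two relations and p-values; ``determined`` is False
    when either comparison had fewer than two usable observations."""

    algorithm_id: str
    target: str
    silo_id: int
    relation_vs_centralized: str | None
    relation_vs_local: str | None
    p_centralized: float
    p_local: float
    determined: bool = True


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    config: ComparisonConfig = ComparisonConfig(),
    higher_better: bool = True,
) -> tuple[float, float, str]:
    """Independent two-sample t-test (pooled variance by default) with the
    relation of ``a`` to ``b``: *equal* if p >= alpha, else decided by the
    means under the metric's orientation.

    Degenerate inputs: identical constant samples -> (0, 1, equal); constant
    samples with different means -> p = 0 and the mean decides.
    """
    a = np.asarray([x for x in np.asarray(a, dtype=float) if np.isfinite(x)])
    b = np.asarray([x for x in np.asarray(b, dtype=float) if np.isfinite(x)])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 finite observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0, "equal"
        t = np.inf if a[0] > b[0] else -np.inf
        p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=config.equal_variance)
        t, p = float(t), float(p)
    if p >= config.alpha:
        return t, p, "equal"
    a_wins = a.mean() > b.mean() if higher_better else a.mean() < b.mean()
    return t, p, "better" if a_wins else "worse"


def build_comparison_cells(
    records: Sequence[MetricRecord],
    config: ComparisonConfig = ComparisonConfig(),
) -> list[ComparisonCell]:
    """One :class:`ComparisonCell` per (algorithm, target, silo): the
    distributed model's driver-metric values over repetitions against the
    centralized and the local models'.  NaN (flagged) metric values are
    excluded; a side with fewer than two values yields an undetermined
    cell."""
    df = records_to_frame(records)
    cells = []
    for (algo, target, silo), g in df.groupby(
        ["algorithm_id", "target", "silo_id"], sort=True
    ):
        task = g["task"].iloc[0]
        metric = config.driver_metric[task]
        higher = config.orientation[metric] == "higher_better"
        samples = {
            kind: g.loc[g["model_kind"] == kind, metric].dropna().to_numpy()
            for kind in ("distributed", "centralized", "local")
        }
        d = samples["distributed"]
        determined = all(len(s) >= 2 for s in samples.values())
        if not determined:
            cells.append(
                ComparisonCell(algo, target, int(silo), None, None,
                               np.nan, np.nan, determined=False)
            )
            continue
        _, p_c, rel_c = two_sample_t(d, samples["centralized"], config, higher)
        _, p_l, rel_l = two_sample_t(d, samples["local"], config, higher)
        cells.append(
            ComparisonCell(algo, target, int(silo), rel_c, rel_l, p_c, p_l)
        )
    return cells


@dataclass
class ContingencyTable:
    """Per-algorithm 3x3 relation counts plus the grand total."""

    counts: pd.DataFrame  # index (algorithm, vs_centralized), columns RELATIONS + row_total
    grand_total: int
    n_undetermined: int = 0

    def formatted(self) -> pd.DataFrame:
        """Counts with percentages of the grand total, 1 decimal place,
        in the ``n (pct)`` style."""
        def fmt(n):
            pct = 100.0 * n / self.grand_total if self.grand_total else 0.0
            return f"{int(n)} ({pct:.1f})"

        return self.counts.map(fmt)


def build_contingency(cells: Sequence[ComparisonCell]) -> ContingencyTable:
    """Tally determined cells into per-algorithm 3x3 tables (rows: relation
    vs centralized; columns: relation vs local) with row totals and a grand
    total.  Empty input yields an all-zero table."""
    determined = [c for c in cells if c.determined]
    algos = sorted({c.algorithm_id for c in determined}) or []
    index = pd.MultiIndex.from_product(
        [algos, RELATIONS], names=["algorithm_id", "vs_centralized"]
    )
    counts = pd.DataFrame(0, index=index, columns=list(RELATIONS) + ["row_total"])
    for c in determined:
        counts.loc[(c.algorithm_id, c.relation_vs_centralized), c.relation_vs_local] += 1
        counts.loc[(c.algorithm_id, c.relation_vs_centralized), "row_total"] += 1
    return ContingencyTable(
        counts=counts,
        grand_total=len(determined),
        n_undetermined=len(cells) - len(determined),
    )


def summarize_overall(
    records: Sequence[MetricRecord],
    config: ComparisonConfig = ComparisonConfig(),
) -> pd.DataFrame:
    """Aggregate summary per metric x model kind: mean, SD, n, 95% CI
    (normal approximation, mean +- 1.96 SD/sqrt(n)) and the p-values of the
    pooled distributed-vs-centralized and distributed-vs-local t-tests over
    all records of that metric."""
    df = records_to_frame(records)
    metric_cols = [c for c in ("AUROC", "AUPRC", "RMSE", "MAE") if c in df.columns]
    rows = []
    for metric in metric_cols:
        sub = df[df[metric].notna()]
        pooled = {
            kind: sub.loc[sub["model_kind"] == kind, metric].to_numpy()
            for kind in ("distributed", "centralized", "local")
        }
        pvals = {}
        for other in ("centralized", "local"):
            if len(pooled["distributed"]) >= 2 and len(pooled[other]) >= 2:
                _, p, _ = two_sample_t(pooled["distributed"], pooled[other], config)
                pvals[other] = p
            else:
                pvals[other] = np.nan
        for kind, vals in pooled.items():
            n = len(vals)
            if n == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else np.nan
            half = 1.96 * sd / np.sqrt(n) if n > 1 else np.nan
            rows.append({
                "metric": metric,
                "model_kind": kind,
                "mean": mean,
                "sd": sd,
                "n": n,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "p_vs_centralized": pvals["centralized"] if kind == "distributed" else np.nan,
                "p_vs_local": pvals["local"] if kind == "distributed" else np.nan,
            })
    return pd.DataFrame(rows)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in the
    comparison pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
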