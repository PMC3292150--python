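"""Confusion rates, cluster-separability index, and the comparison report.

The separability index here follows the source formulation exactly: the
numerator is the sum over clusters of the *sample SD* of member-to-centroid
distances and the denominator is the distance between the two cluster
centroids.  That differs from the canonical Davies-Bouldin index (mean
scatter, pairwise max, average over clusters), which is provided as
:func:`dbi_canonical` for comparison.

Display arithmetic rounds half-up to two decimals, and improvement deltas
are taken between *rounded* column means, reproducing printed-table
arithmetic; unrounded values are retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core import FatigueClass, FeatureSeries, LabelSeries, ValidationError
from .features import rolling_std

__all__ = [
    "ConfusionMatrix",
    "RateSet",
    "ComparisonReport",
    "round_half_up",
    "rates",
    "dbi",
    "dbi_canonical",
    "dbi_window_sweep",
    "summarize",
    "improvements",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Second-denominated confusion counts for one class pair.

    ``a``: correct negatives, ``b``: incorrect positives, ``c``: incorrect
    negatives, ``d``: correct positives (negative = less severe class,
    positive = more severe class).  Counts may be fractional (averages).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class RateSet:
    """Derived rates; a rate with a zero denominator is None (undefined)."""

    tp: float | None
    fp: float | None
    tn: float | None
    fn: float | None
    precision: float | None
    accuracy: float | None


def rates(cm: ConfusionMatrix) -> RateSet:
    """Exact confusion rates.

    tp = d/(c+d), fp = b/(a+b), tn = a/(a+b), fn = c/(c+d),
    precision = d/(b+d), accuracy = (a+d)/(a+b+c+d).
    """
    if cm.total <= 0:
        raise ValidationError("empty confusion matrix")

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    return RateSet(
        tp=ratio(cm.d, cm.c + cm.d),
        fp=ratio(cm.b, cm.a + cm.b),
        tn=ratio(cm.a, cm.a + cm.b),
        fn=ratio(cm.c, cm.c + cm.d),
        precision=ratio(cm.d, cm.b + cm.d),
        accuracy=(cm.a + cm.d) / cm.total,
    )


def _as_clusters(clusters) -> list[np.ndarray]:
    out = []
    for members in clusters:
        arr = np.asarray(members, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.size == 0:
            raise ValidationError("clusters must be non-empty")
        out.append(arr)
    if len(out) < 2:
        raise ValidationError("need at least two clusters")
    return out


def dbi(clusters) -> float:
    """Separability index, as formulated in the source: sum of per-cluster
    sample SDs of member-to-centroid distances over the distance between the
    two centroids.  Lower is better.  Defined for exactly two clusters
    (see :func:`dbi_canonical` for the multi-cluster classic)."""
    cl = _as_clusters(clusters)
    if len(cl) != 2:
        raise ValidationError(
            "this index is defined for two clusters; use dbi_canonical otherwise"
        )
    centroids = [c.mean(axis=0) for c in cl]
    numerator = 0.0
    for members, centroid in zip(cl, centroids):
        dist = np.linalg.norm(members - centroid, axis=1)
        numerator += float(dist.std(ddof=1)) if dist.size > 1 else 0.0
    denominator = float(np.linalg.norm(centroids[0] - centroids[1]))
    if denominator == 0.0:
        raise ValidationError("coincident centroids: separability undefined")
    return numerator / denominator


def dbi_canonical(clusters) -> float:
    """Classic Davies-Bouldin index (mean scatter, max pairwise ratio)."""
    cl = _as_clusters(clusters)
    centroids = [c.mean(axis=0) for c in cl]
    scatter = [float(np.linalg.norm(c - m, axis=1).mean())
               for c, m in zip(cl, centroids)]
    k = len(cl)
    worst = []
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            sep = float(np.linalg.norm(centroids[i] - centroids[j]))
            if sep == 0.0:
                raise ValidationError("coincident centroids: index undefined")
            ratios.append((scatter[i] + scatter[j]) / sep)
        worst.append(max(ratios))
    return float(np.mean(worst))


def dbi_window_sweep(
    unified: FeatureSeries,
    labels: LabelSeries,
    pair: tuple[FatigueClass, FatigueClass],
    spans: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict[int, float]:
    """Separability of the two classes after rolling-SD at each span.

    Span 1 uses the raw unified values (the rolling SD of a single point is
    identically zero, which would make the sweep meaningless).
    """
    out: dict[int, float] = {}
    for span in spans:
        series = unified if span == 1 else rolling_std(unified, span)
        groups: dict[int, list[float]] = {int(c): [] for c in pair}
        for t, v in zip(series.times, series.values):
            sec = int(np.floor(t - labels.start_time + 1e-9))
            if not 0 <= sec < len(labels):
                continue
            lab = int(labels.labels[sec])
            if lab in groups:
                groups[lab].append(v)
        clusters = [groups[int(c)] for c in pair]
        if any(len(c) == 0 for c in clusters):
            raise ValidationError(
                f"span {span}: a class of the pair has no seconds"
            )
        out[span] = dbi(clusters)
    return out


@dataclass
class ComparisonReport:
    """Per-subject percent-correct table with column summaries.

    ``means``/``sds`` are unrounded; ``display`` carries the 2-dp half-up
    rounded rows appended as AVG / STDEV.
    """

    table: pd.DataFrame
    means: pd.Series = field(init=False)
    sds: pd.Series = field(init=False)
    display: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.table.shape[0] < 2:
            raise ValidationError("need at least two subjects")
        if self.table.isna().any().any():
            raise ValidationError("table contains missing cells")
        for col in self.table.columns:
            if self.table[col].size == 0:
                raise ValidationError(f"empty column {col!r}")
        self.means = self.table.mean(axis=0)
        self.sds = self.table.std(axis=0, ddof=1)
        display = self.table.copy()
        display.loc["AVG"] = [round_half_up(v) for v in self.means]
        display.loc["STDEV"] = [round_half_up(v) for v in self.sds]
        self.display = display

    def rounded_mean(self, column: str) -> float:
        return round_half_up(float(self.means[column]))

    def rounded_sd(self, column: str) -> float:
        return round_half_up(float(self.sds[column]))


def summarize(table: pd.DataFrame) -> ComparisonReport:
    """Column means and sample SDs of a per-subject percent-correct table."""
    return ComparisonReport(table=table.astype(float))


def improvements(report: ComparisonReport,
                 reference_feature: str = "spectro_std") -> dict[str, dict]:
    """Improvement of the reference column over each other column.

    Deltas are differences of the 2-dp rounded column means (printed-table
    arithmetic).  ``p_value`` comes from a two-sided paired t-test across
    subjects; it is NaN when the paired differences have zero variance.
    The ``average_of_others`` entry compares against the rounded mean of the
    other columns' rounded means, with the t-test pairing the reference
    column against the per-subject mean of the other columns.
    """
    if reference_feature not in report.table.columns:
        raise ValidationError(
            f"reference column {reference_feature!r} not in report"
        )
    ref_mean = report.rounded_mean(reference_feature)
    ref_col = report.table[reference_feature].to_numpy(dtype=float)
    others = [c for c in report.table.columns if c != reference_feature]
    out: dict[str, dict] = {}
    for col in others:
        other_col = report.table[col].to_numpy(dtype=float)
        out[col] = {
            "delta": round_half_up(ref_mean - report.rounded_mean(col)),
            "p_value": _paired_p(ref_col, other_col),
            "test": "paired t-test (two-sided)",
        }
    if others:
        other_avg = round_half_up(
            float(np.mean([report.rounded_mean(c) for c in others]))
        )
        row_mean = report.table[others].to_numpy(dtype=float).mean(axis=1)
        out["average_of_others"] = {
            "delta": round_half_up(ref_mean - other_avg),
            "p_value": _paired_p(ref_col, row_mean),
            "test": "paired t-test (two-sided)",
        }
    return out


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    diff = x - y
    if np.allclose(diff, diff[0]):
        return float("nan")
    return float(stats.ttest_rel(x, y).pvalue)
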