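"""Binary outcome contrasts, per-metric screening tests, and ROC/AUC machinery.

Each T cell metric is screened in binary contrasts between outcome groups
(relapse vs the rest, any GVHD vs none, grade >= 2 GVHD vs the rest) with a
two-sided Welch t test for linear-scale metrics or a Mann-Whitney rank test
for logarithmic ones; metrics passing p < alpha proceed to ROC analysis. The
AUC is computed rank-based (Mann-Whitney equivalence: the probability that a
random positive outranks a random negative, ties counted half) and its
significance from the tie-corrected normal approximation of the U null, with
an optional exact permutation p for small problems.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, MetricScale, OutcomeGroup, SampleRecord

__all__ = [
    "Direction",
    "ContrastSpec",
    "DEFAULT_CONTRASTS",
    "LabeledValues",
    "ROCResult",
    "assign_labels",
    "screen_test",
    "auc_rank",
    "roc_points",
    "screen_metrics",
]


class Direction(str, enum.Enum):
    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


@dataclass(frozen=True)
class ContrastSpec:
    """A binary outcome contrast: which groups count as positive vs negative.

    Samples from groups on neither side are excluded from the analysis, so the
    three default contrasts make no claim about, e.g., where relapse patients
    sit in the GVHD comparisons — membership is configuration, not constant.
    """

    name: str
    positive_groups: frozenset[OutcomeGroup]
    negative_groups: frozenset[OutcomeGroup]

    def __post_init__(self) -> None:
        if not self.positive_groups or not self.negative_groups:
            raise ValueError(f"contrast {self.name!r}: both group sets must be non-empty")
        if self.positive_groups & self.negative_groups:
            raise ValueError(f"contrast {self.name!r}: group sets must be disjoint")

    def label_of(self, group: OutcomeGroup) -> int | None:
        if group in self.positive_groups:
            return 1
        if group in self.negative_groups:
            return 0
        return None


DEFAULT_CONTRASTS: dict[str, ContrastSpec] = {
    "relapse": ContrastSpec(
        "relapse",
        frozenset({OutcomeGroup.RELAPSE}),
        frozenset({OutcomeGroup.NO_GVHD, OutcomeGroup.GRADE1, OutcomeGroup.GRADE2_4}),
    ),
    "any_gvhd": ContrastSpec(
        "any_gvhd",
        frozenset({OutcomeGroup.GRADE1, OutcomeGroup.GRADE2_4}),
        frozenset({OutcomeGroup.NO_GVHD}),
    ),
    "grade2plus": ContrastSpec(
        "grade2plus",
        frozenset({OutcomeGroup.GRADE2_4}),
        frozenset({OutcomeGroup.NO_GVHD, OutcomeGroup.GRADE1}),
    ),
}


@dataclass
class LabeledValues:
    """Metric values with binary labels and the owning patient ids (the unit
    identifiers for unit-aware cross-validation)."""

    values: np.ndarray
    labels: np.ndarray
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        if not (len(self.values) == len(self.labels) == len(self.unit_ids)):
            raise ValueError("values, labels and unit_ids must have equal length")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"degenerate class composition: {self.n_pos} positives, {self.n_neg} negatives"
            )


@dataclass
class ROCResult:
    """ROC points, trapezoidal AUC, and AUC significance for one metric/contrast."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)
    thresholds: np.ndarray
    auc: float
    p_value: float
    direction: Direction


def assign_labels(
    cohort: Cohort,
    metric: str,
    contrast: ContrastSpec,
    samples: list[SampleRecord] | None = None,
) -> LabeledValues:
    """One labeled value per retained sample possessing ``metric``.

    Samples from patients outside the contrast's groups, and samples missing
    the metric, are excluded. Raises if either class ends up empty.
    """
    if metric not in cohort.metric_definitions:
        raise KeyError(f"metric {metric!r} not declared in the cohort")
    if samples is None:
        samples = cohort.samples
    values, labels, units = [], [], []
    for s in samples:
        label = contrast.label_of(cohort.patients[s.patient_id].outcome_group)
        if label is None or metric not in s.metrics:
            continue
        values.append(s.metrics[metric])
        labels.append(label)
        units.append(s.patient_id)
    lv = LabeledValues(np.array(values, dtype=float), np.array(labels), np.array(units, dtype=object))
    lv.require_both_classes()
    return lv


def screen_test(group_a, group_b, scale: MetricScale | str) -> tuple[float, float]:
    """Two-sided screening test between two groups of metric values.

    Linear-scale metrics get a Welch unequal-variance t test; logarithmic
    ones a Mann-Whitney rank test. Two identical constant groups return
    (0.0, 1.0) by convention; zero within-group variance with unequal means
    returns (+/-inf, 0.0) rather than failing.
    """
    scale = MetricScale(scale)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if scale is MetricScale.LINEAR:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("Welch t test needs at least 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return 0.0, 1.0
            return (math.copysign(math.inf, a[0] - b[0]), 0.0)
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("Mann-Whitney test needs at least 1 value per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _oriented(values: np.ndarray, direction: Direction) -> np.ndarray:
    return values if direction is Direction.HIGHER_IS_POSITIVE else -values


def _mw_normal_p(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Two-sided p for the Mann-Whitney U under the tie-corrected normal null."""
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def auc_rank(
    lv: LabeledValues,
    direction: Direction = Direction.HIGHER_IS_POSITIVE,
    method: str = "normal",
    max_exact: int = 200_000,
) -> tuple[float, float]:
    """Rank-based AUC with its significance.

    AUC = (concordant + 0.5 * tied) / (n_pos * n_neg) over all
    positive-negative pairs, computed from mid-ranks. ``method="normal"``
    (default) gives the two-sided tie-corrected normal-approximation
    Mann-Whitney p; ``method="exact"`` enumerates all label permutations when
    there are at most ``max_exact`` of them and falls back to the normal
    approximation otherwise.
    """
    lv.require_both_classes()
    x = _oriented(lv.values, Direction(direction))
    pos_mask = lv.labels == 1
    n1, n2 = lv.n_pos, lv.n_neg
    ranks = stats.rankdata(x)
    u = float(ranks[pos_mask].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n2)
    if method == "exact" and math.comb(n1 + n2, n1) <= max_exact:
        p = _exact_permutation_p(ranks, n1, abs(auc - 0.5))
    else:
        p = _mw_normal_p(u, n1, n2, x)
    return auc, p


def _exact_permutation_p(ranks: np.ndarray, n_pos: int, observed_dev: float) -> float:
    """Exact two-sided permutation p for the AUC: the fraction of all
    positive-label placements whose |AUC - 0.5| reaches the observed deviation.
    Valid in the presence of ties (mid-ranks are permuted as-is)."""
    n = len(ranks)
    rank_floor = n_pos * (n_pos + 1) / 2.0
    denom = n_pos * (n - n_pos)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_pos):
        auc = (ranks[list(combo)].sum() - rank_floor) / denom
        total += 1
        if abs(auc - 0.5) >= observed_dev - 1e-12:
            hits += 1
    return hits / total


def roc_points(lv: LabeledValues, direction: Direction = Direction.HIGHER_IS_POSITIVE) -> ROCResult:
    """ROC curve by threshold sweep over the distinct (oriented) values.

    Ties are grouped at a single threshold, so the trapezoidal area equals the
    rank-based AUC of :func:`auc_rank` exactly (to floating point).
    """
    direction = Direction(direction)
    lv.require_both_classes()
    x = _oriented(lv.values, direction)
    y = lv.labels
    order = np.argsort(-x, kind="mergesort")
    x_sorted, y_sorted = x[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(x_sorted))[0], len(x_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / lv.n_pos]
    fpr = np.r_[0.0, fp / lv.n_neg]
    thresholds = np.r_[np.inf, x_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    _, p = auc_rank(lv, direction)
    return ROCResult(
        points=np.column_stack([fpr, tpr]),
        thresholds=thresholds,
        auc=auc,
        p_value=p,
        direction=direction,
    )


def screen_metrics(
    cohort: Cohort,
    window_samples: list[SampleRecord],
    contrast: ContrastSpec,
    alpha: float = 0.05,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Screen every metric in the windowed samples against a contrast.

    Returns a DataFrame (metric, n_pos, n_neg, statistic, p_value, passed)
    with passed <=> p < alpha, strict, with no multiplicity adjustment.
    Degenerate metrics (constant in both groups, or missing a class) yield
    p = 1 / NaN without aborting the sweep.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if metrics is None:
        metrics = cohort.metric_names
    rows = []
    for metric in metrics:
        scale = cohort.metric_definitions[metric].scale
        try:
            lv = assign_labels(cohort, metric, contrast, window_samples)
            a = lv.values[lv.labels == 1]
            b = lv.values[lv.labels == 0]
            stat, p = screen_test(a, b, scale)
            n_pos, n_neg = lv.n_pos, lv.n_neg
        except ValueError:
            stat, p, n_pos, n_neg = math.nan, math.nan, 0, 0
        rows.append(
            {
                "metric": metric,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "statistic": stat,
                "p_value": p,
                "passed": bool(p < alpha) if not math.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)
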