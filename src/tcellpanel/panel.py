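"""Multiplicative directed-ECDF combined biomarker score with unit-aware LOOCV.

The multiparameter score transforms each metric through its empirical CDF
evaluated on the pooled training values (mid-rank convention, clamped away
from 0 and 1), orients each transform so that its single-variable AUC is at
least 0.5 ("higher" vs "lower" chosen by AUC-ROC), and multiplies the
directed factors into one combined score per sample. Because every step is
rank-based, the score is invariant to strictly increasing transforms of any
metric. Generalization is estimated by leave-one-out cross-validation with
the patient as the default unit (repeated draws from one patient are not
exchangeable, so leaving out single samples would leak patient identity);
directions and ECDFs are refitted inside every fold.

The module exposes both the low-level operations (``mid_rank_ecdf``,
``fit_directed_ecdf``, ``panel_score``, ``loocv_combined_auc``) and a
model/results pair, :class:`CombinedScoreModel` / :class:`CombinedScoreResults`,
for the fit -> inspect -> cross-validate workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .cohort import Cohort, SampleRecord
from .screening import ContrastSpec, Direction, LabeledValues, assign_labels, auc_rank

__all__ = [
    "DirectedECDF",
    "PanelModel",
    "CVResult",
    "mid_rank_ecdf",
    "fit_directed_ecdf",
    "directed_value",
    "panel_score",
    "loocv_combined_auc",
    "CombinedScoreModel",
    "CombinedScoreResults",
]


def mid_rank_ecdf(train_values, x):
    """Mid-rank empirical CDF of ``x`` against the training values.

    e(x) = (#{v < x} + 0.5 * #{v = x}) / n, clamped to
    [1/(2n), 1 - 1/(2n)] so values outside the training support never map to
    exactly 0 or 1 (which would zero or saturate the product score).
    Accepts scalar or array ``x``.
    """
    train = np.sort(np.asarray(train_values, dtype=float))
    n = len(train)
    if n == 0:
        raise ValueError("mid_rank_ecdf requires a non-empty training set")
    xs = np.asarray(x, dtype=float)
    less = np.searchsorted(train, xs, side="left")
    less_eq = np.searchsorted(train, xs, side="right")
    e = (less + 0.5 * (less_eq - less)) / n
    e = np.clip(e, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return float(e) if np.isscalar(x) or np.ndim(x) == 0 else e


@dataclass
class DirectedECDF:
    """One metric's oriented ECDF transform: direction chosen by AUC-ROC so
    that the oriented training AUC is >= 0.5."""

    metric: str
    train_values: np.ndarray
    direction: Direction
    train_auc: float

    def __post_init__(self) -> None:
        self.train_values = np.sort(np.asarray(self.train_values, dtype=float))
        if len(self.train_values) == 0:
            raise ValueError(f"DirectedECDF for {self.metric!r}: empty training values")

    def __call__(self, x):
        return directed_value(self, x)


def fit_directed_ecdf(lv: LabeledValues, metric: str) -> DirectedECDF:
    """Fit one metric's directed ECDF: orientation with AUC >= 0.5 wins
    (exact tie -> higher_is_positive); training values pool both classes."""
    lv.require_both_classes()
    auc_higher, _ = auc_rank(lv, Direction.HIGHER_IS_POSITIVE)
    if auc_higher >= 0.5:
        direction, train_auc = Direction.HIGHER_IS_POSITIVE, auc_higher
    else:
        direction, train_auc = Direction.LOWER_IS_POSITIVE, 1.0 - auc_higher
    return DirectedECDF(metric=metric, train_values=lv.values, direction=direction, train_auc=train_auc)


def directed_value(model: DirectedECDF, x):
    """Oriented ECDF factor in (0, 1); the two orientations are exact complements."""
    e = mid_rank_ecdf(model.train_values, x)
    if model.direction is Direction.HIGHER_IS_POSITIVE:
        return e
    return 1.0 - e


@dataclass
class PanelModel:
    """An ordered set of fitted directed ECDFs whose product is the combined score."""

    components: list[DirectedECDF]

    def __post_init__(self) -> None:
        names = [c.metric for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("panel metrics must be unique")

    @property
    def metrics(self) -> list[str]:
        return [c.metric for c in self.components]


def panel_score(panel: PanelModel, sample_metrics: dict[str, float]) -> float:
    """Combined score for one sample: the product of its directed ECDF factors.

    Every panel metric must be present; a missing metric is an error (no
    silent imputation). Strictly positive by the ECDF clamp.
    """
    score = 1.0
    for comp in panel.components:
        if comp.metric not in sample_metrics:
            raise KeyError(f"sample is missing panel metric {comp.metric!r}")
        score *= directed_value(comp, sample_metrics[comp.metric])
    return score


@dataclass
class CVResult:
    """Leave-one-out cross-validation output: every unit scored exactly once
    by a model fitted without it, plus the AUC over the held-out scores."""

    held_out: pd.DataFrame  # columns: unit_id, label, score (one row per sample)
    auc: float
    p_value: float
    n_units: int
    unit: str
    # per-fold fitted components (held-out unit -> its scoring panel), kept
    # only on request; lets callers audit that no unit's own data reached the
    # model that scored it
    fold_models: dict | None = None

    def summary(self) -> str:
        tbl = SimpleTable(
            [
                ["cross-validation unit", self.unit],
                ["units held out", str(self.n_units)],
                ["held-out samples", str(len(self.held_out))],
                ["LOOCV AUC", f"{self.auc:.4f}"],
                ["AUC p-value", f"{self.p_value:.4g}"],
            ],
            title="Leave-one-out cross-validated combined score",
        )
        return str(tbl)


def _fold_arrays(
    cohort: Cohort,
    window_samples: list[SampleRecord],
    metrics: list[str],
    contrast: ContrastSpec,
):
    """Dense per-sample arrays restricted to samples that carry every panel
    metric and belong to the contrast."""
    rows, labels, units = [], [], []
    for s in window_samples:
        label = contrast.label_of(cohort.patients[s.patient_id].outcome_group)
        if label is None:
            continue
        if any(m not in s.metrics for m in metrics):
            continue
        rows.append([s.metrics[m] for m in metrics])
        labels.append(label)
        units.append(s.patient_id)
    if not rows:
        raise ValueError("no samples carry all panel metrics within the contrast")
    return (
        np.asarray(rows, dtype=float),
        np.asarray(labels, dtype=int),
        np.asarray(units, dtype=object),
    )


def fit_panel(
    cohort: Cohort,
    window_samples: list[SampleRecord],
    metrics: list[str],
    contrast: ContrastSpec,
) -> PanelModel:
    """Fit the directed ECDF panel on all (windowed, contrast-restricted) samples."""
    x, y, units = _fold_arrays(cohort, window_samples, metrics, contrast)
    components = [
        fit_directed_ecdf(LabeledValues(x[:, j], y, units), m) for j, m in enumerate(metrics)
    ]
    return PanelModel(components)


def _score_matrix(panel: PanelModel, x: np.ndarray) -> np.ndarray:
    scores = np.ones(len(x))
    for j, comp in enumerate(panel.components):
        scores *= np.asarray(directed_value(comp, x[:, j]))
    return scores


def loocv_combined_auc(
    cohort: Cohort,
    window_samples: list[SampleRecord],
    metrics: list[str],
    contrast: ContrastSpec,
    unit: str = "patient",
    refit_directions: bool = True,
    keep_fold_models: bool = False,
) -> CVResult:
    """Leave-one-unit-out cross-validated combined-score AUC.

    For every held-out unit (patient by default; ``unit="sample"`` for
    per-draw folds) the directed ECDFs — directions included, unless
    ``refit_directions=False`` pins the directions fitted on the full data —
    are refitted on the remaining units only, the held-out unit's samples are
    scored by the product rule, and the AUC is computed over all held-out
    scores. A fold that loses one class entirely is an error naming the unit.
    """
    if unit not in ("patient", "sample"):
        raise ValueError(f"unit must be 'patient' or 'sample', got {unit!r}")
    x, y, pids = _fold_arrays(cohort, window_samples, metrics, contrast)
    fold_ids = pids if unit == "patient" else np.arange(len(y)).astype(object)
    unique_units = pd.unique(fold_ids)
    unit_labels = {u: y[fold_ids == u] for u in unique_units}
    n_pos_units = sum(1 for u in unique_units if unit_labels[u].max() == 1)
    n_neg_units = len(unique_units) - n_pos_units
    if n_pos_units < 2 or n_neg_units < 2:
        raise ValueError(
            f"LOOCV needs >=2 units per class; got {n_pos_units} positive, {n_neg_units} negative"
        )

    global_directions = None
    if not refit_directions:
        global_directions = [
            fit_directed_ecdf(LabeledValues(x[:, j], y, pids), m).direction
            for j, m in enumerate(metrics)
        ]

    frames = []
    fold_models: dict = {} if keep_fold_models else None
    for u in unique_units:
        held = fold_ids == u
        train = ~held
        y_train = y[train]
        if y_train.max() == 0 or y_train.min() == 1:
            raise ValueError(f"fold holding out unit {u!r} loses one class entirely")
        components = []
        for j, m in enumerate(metrics):
            comp = fit_directed_ecdf(LabeledValues(x[train, j], y_train, pids[train]), m)
            if global_directions is not None and comp.direction is not global_directions[j]:
                comp = DirectedECDF(m, x[train, j], global_directions[j], 1.0 - comp.train_auc)
            components.append(comp)
        fold_panel = PanelModel(components)
        if keep_fold_models:
            fold_models[u] = fold_panel
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": pids[held],
                    "label": y[held],
                    "score": _score_matrix(fold_panel, x[held]),
                }
            )
        )
    held_out = pd.concat(frames, ignore_index=True)
    lv = LabeledValues(
        held_out["score"].to_numpy(), held_out["label"].to_numpy(), held_out["unit_id"].to_numpy()
    )
    auc, p = auc_rank(lv, Direction.HIGHER_IS_POSITIVE)
    return CVResult(
        held_out=held_out, auc=auc, p_value=p, n_units=len(unique_units), unit=unit,
        fold_models=fold_models,
    )


# ---------------------------------------------------------------------------
# model / results interface


class CombinedScoreModel:
    """Combined directed-ECDF score model for a metric panel and outcome contrast.

    Parameters
    ----------
    cohort : Cohort
        Validated cohort (patients, samples, metric definitions).
    metrics : list of str
        Panel metric names; every scored sample must carry all of them.
    contrast : ContrastSpec
        Positive/negative outcome-group memberships.
    window_samples : list of SampleRecord, optional
        Sample subset to analyze (e.g. from ``select_window`` or a
        diagnosis-day-normalized selection); defaults to all samples.

    Examples
    --------
    >>> model = CombinedScoreModel(cohort, ["pct_DPT", "pct_Treg"],
    ...                            DEFAULT_CONTRASTS["grade2plus"],
    ...                            select_window(cohort, 7, 17))
    >>> res = model.fit()
    >>> print(res.summary())
    >>> cv = model.loocv(unit="patient")
    """

    def __init__(
        self,
        cohort: Cohort,
        metrics: list[str],
        contrast: ContrastSpec,
        window_samples: list[SampleRecord] | None = None,
    ) -> None:
        self.cohort = cohort
        self.metrics = list(metrics)
        self.contrast = contrast
        self.window_samples = list(cohort.samples) if window_samples is None else list(window_samples)
        unknown = [m for m in self.metrics if m not in cohort.metric_definitions]
        if unknown:
            raise KeyError(f"unknown metrics: {unknown}")

    def fit(self) -> "CombinedScoreResults":
        panel = fit_panel(self.cohort, self.window_samples, self.metrics, self.contrast)
        x, y, units = _fold_arrays(self.cohort, self.window_samples, self.metrics, self.contrast)
        scores = _score_matrix(panel, x)
        train_auc, train_p = auc_rank(
            LabeledValues(scores, y, units), Direction.HIGHER_IS_POSITIVE
        )
        return CombinedScoreResults(self, panel, scores, y, units, train_auc, train_p)

    def loocv(self, unit: str = "patient", refit_directions: bool = True) -> CVResult:
        return loocv_combined_auc(
            self.cohort, self.window_samples, self.metrics, self.contrast,
            unit=unit, refit_directions=refit_directions,
        )


class CombinedScoreResults:
    """Fitted panel: per-metric directions and training AUCs, in-sample
    combined scores, and the apparent (training) combined AUC."""

    def __init__(self, model, panel, scores, labels, unit_ids, train_auc, train_p) -> None:
        self.model = model
        self.panel = panel
        self.scores = scores
        self.labels = labels
        self.unit_ids = unit_ids
        self.train_auc = train_auc
        self.train_p = train_p

    def component_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [c.metric for c in self.panel.components],
                "direction": [c.direction.value for c in self.panel.components],
                "train_auc": [c.train_auc for c in self.panel.components],
            }
        )

    def score(self, sample_metrics: dict[str, float]) -> float:
        """Combined score for a new sample's metric mapping."""
        return panel_score(self.panel, sample_metrics)

    def summary(self) -> str:
        comp = self.component_table()
        rows = [[r.metric, r.direction, f"{r.train_auc:.4f}"] for r in comp.itertuples()]
        tbl = SimpleTable(
            rows,
            headers=["metric", "direction", "train AUC"],
            title=(
                f"Combined ECDF-product score — contrast {self.model.contrast.name!r} "
                f"(n={len(self.scores)} samples; apparent AUC {self.train_auc:.4f}, "
                f"p={self.train_p:.3g})"
            ),
        )
        return str(tbl)
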