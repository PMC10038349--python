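"""Seeded synthetic data generators with known ground truth.

Emulates the structure of a 35-recipient longitudinal allo-HCT cohort —
weekly-ish blood draws every 4 to 6 days over 100 days of follow-up, four
outcome groups, GVHD diagnosis days averaging day 54 — with per-metric,
per-group location shifts of known size so that the screening/ROC/combined-
score pipeline can be validated against analytic answers. Every metric is a
strictly increasing transform of an equal-variance latent normal with group
shift delta, so the single-metric ground-truth AUC between two groups is
exactly Phi(delta_diff / sqrt(2)) and mixtures of groups average those
pairwise AUCs. Also provides multinomial clone-table generation with
controllable evenness, and a xenotransplant-style mouse cohort (weekly blood
DPT% and weight loss, lethal vs nonlethal arms) with the published 0-4
weight-loss GVHD score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import (
    Cohort,
    MetricDefinition,
    MetricKind,
    MetricScale,
    OutcomeGroup,
    PatientRecord,
    SampleRecord,
)
from .screening import DEFAULT_CONTRASTS, ContrastSpec

__all__ = [
    "MetricSimSpec",
    "CohortSimConfig",
    "CloneSimConfig",
    "MouseSimConfig",
    "simulate_cohort",
    "simulate_clone_table",
    "simulate_mouse_cohort",
    "theoretical_auc",
    "ground_truth_table",
    "gvhd_weight_score",
    "draw_metric_values",
    "config_from_dict",
    "config_to_dict",
]

GROUPS = (
    OutcomeGroup.RELAPSE,
    OutcomeGroup.NO_GVHD,
    OutcomeGroup.GRADE1,
    OutcomeGroup.GRADE2_4,
)


@dataclass(frozen=True)
class MetricSimSpec:
    """Generator spec for one metric.

    family 'lognormal' (counts): value = exp(mu + sigma * z);
    family 'logitnormal' (frequencies): value = 100 * expit(mu + sigma * z);
    with z ~ N(shift[group], 1). Both transforms are strictly increasing, so
    rank-based statistics of the metric equal those of the latent normal.
    """

    name: str
    family: str  # 'lognormal' | 'logitnormal'
    mu: float
    sigma: float
    shifts: dict[str, float] = field(default_factory=dict)  # group value -> delta

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "logitnormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def shift(self, group: OutcomeGroup) -> float:
        return self.shifts.get(group.value, 0.0)

    def definition(self) -> MetricDefinition:
        if self.family == "logitnormal":
            return MetricDefinition(self.name, MetricKind.FREQUENCY, MetricScale.LINEAR)
        return MetricDefinition(self.name, MetricKind.COUNT, MetricScale.LOGARITHMIC)


def default_metric_panel() -> list[MetricSimSpec]:
    """Eleven-metric panel emulating the clinical flow panel: five metrics
    carry group effects (the predictive five: CD45RO count, blasting CD45RO%,
    Treg%, CD8%, DPT%), six are null. Shift sizes give single-metric AUCs in
    the 0.64-0.78 range typical of the screened metrics."""
    up = "grade2_4"
    return [
        MetricSimSpec("count_CD45RO", "lognormal", mu=5.5, sigma=1.0,
                      shifts={"relapse": -0.8}),
        MetricSimSpec("count_CD4", "lognormal", mu=5.0, sigma=1.0),
        MetricSimSpec("count_CD8", "lognormal", mu=4.8, sigma=1.0),
        MetricSimSpec("count_Treg", "lognormal", mu=3.5, sigma=1.0),
        MetricSimSpec("pct_CD4", "logitnormal", mu=0.4, sigma=0.5),
        MetricSimSpec("pct_CD8", "logitnormal", mu=-0.4, sigma=0.5,
                      shifts={"grade1": 0.5, up: 0.8}),
        MetricSimSpec("pct_DPT", "logitnormal", mu=-3.0, sigma=0.8,
                      shifts={"grade1": 0.8, up: 1.1, "relapse": -0.8}),
        MetricSimSpec("pct_Treg", "logitnormal", mu=-2.5, sigma=0.6,
                      shifts={"grade1": -0.5, up: -0.8}),
        MetricSimSpec("pct_blasting_CD45RO", "logitnormal", mu=-1.5, sigma=0.6,
                      shifts={"grade1": 0.5, up: 0.8}),
        MetricSimSpec("pct_blasting_CD4", "logitnormal", mu=-1.8, sigma=0.6),
        MetricSimSpec("pct_blasting_CD8", "logitnormal", mu=-1.8, sigma=0.6),
    ]


@dataclass
class CohortSimConfig:
    """Study-condition configuration for the synthetic cohort.

    Defaults mirror the emulated study: 35 recipients across four outcome
    groups, draws scheduled every 4-6 days through day 100 with attendance
    probability 0.6 (giving ~12 collected samples per patient), GVHD
    diagnosis days centered on day 54, and one dual-event patient (grade 2-4
    GVHD followed by relapse).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"relapse": 8, "no_gvhd": 10, "grade1": 7, "grade2_4": 10}
    )
    interval_days: tuple[int, int] = (4, 6)
    follow_up_days: int = 100
    attendance: float = 0.6
    metric_specs: list[MetricSimSpec] = field(default_factory=default_metric_panel)
    diagnosis_day_mean: float = 54.0
    diagnosis_day_sd: float = 18.0
    relapse_day_mean: float = 150.0
    relapse_day_sd: float = 60.0
    patient_sd: float = 0.0  # latent patient-level random effect (off by default)
    include_dual_event_patient: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.n_per_group) - {g.value for g in GROUPS}
        if unknown:
            raise ValueError(f"unknown outcome groups {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be non-negative")
        lo, hi = self.interval_days
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid sampling interval {self.interval_days}")
        if lo > self.follow_up_days:
            raise ValueError("sampling interval exceeds follow-up")
        if not 0.0 < self.attendance <= 1.0:
            raise ValueError("attendance must be in (0, 1]")

    def null(self) -> "CohortSimConfig":
        """The declared-null configuration: identical structure, all shifts zero."""
        specs = [replace(s, shifts={}) for s in self.metric_specs]
        return replace(self, metric_specs=specs)

    @property
    def is_null(self) -> bool:
        return all(not any(s.shifts.values()) for s in self.metric_specs)


def draw_metric_values(spec: MetricSimSpec, group: OutcomeGroup, n: int, rng: np.random.Generator,
                       patient_effect: float = 0.0) -> np.ndarray:
    """Draw n values of one metric for one outcome group."""
    z = rng.normal(spec.shift(group) + patient_effect, 1.0, n)
    if spec.family == "lognormal":
        return np.exp(spec.mu + spec.sigma * z)
    return 100.0 * expit(spec.mu + spec.sigma * z)


def theoretical_auc(spec: MetricSimSpec, contrast: ContrastSpec, n_per_group: dict[str, int]) -> float:
    """Exact ground-truth AUC of one metric for a contrast.

    For equal-variance normal latents shifted by delta the two-group AUC is
    Phi(delta / sqrt(2)); a contrast mixing several groups on either side
    averages the pairwise AUCs weighted by expected sample counts (group
    sizes; expected draws per patient are equal across groups).
    """
    pos = [g for g in GROUPS if g in contrast.positive_groups and n_per_group.get(g.value, 0) > 0]
    neg = [g for g in GROUPS if g in contrast.negative_groups and n_per_group.get(g.value, 0) > 0]
    if not pos or not neg:
        raise ValueError(f"contrast {contrast.name!r} has an empty side under these group sizes")
    wp = np.array([n_per_group[g.value] for g in pos], dtype=float)
    wn = np.array([n_per_group[g.value] for g in neg], dtype=float)
    wp /= wp.sum()
    wn /= wn.sum()
    auc = 0.0
    for g, w1 in zip(pos, wp):
        for h, w2 in zip(neg, wn):
            auc += w1 * w2 * norm.cdf((spec.shift(g) - spec.shift(h)) / math.sqrt(2.0))
    return float(auc)


def ground_truth_table(
    config: CohortSimConfig, contrasts: dict[str, ContrastSpec] | None = None
) -> pd.DataFrame:
    """Analytic per-metric, per-contrast ground-truth AUC for a configuration."""
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    rows = []
    for spec in config.metric_specs:
        for cname, contrast in contrasts.items():
            rows.append(
                {
                    "metric": spec.name,
                    "contrast": cname,
                    "theoretical_auc": theoretical_auc(spec, contrast, config.n_per_group),
                }
            )
    return pd.DataFrame(rows)


def _draw_day(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def simulate_cohort(
    config: CohortSimConfig, seed: int | np.random.Generator
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its analytic ground-truth AUC table.

    Per patient: an outcome group, event days (GVHD diagnosis day for the
    GVHD groups, truncated normal around day 54; relapse day within the first
    year for relapse patients), and blood draws scheduled every 4-6 days and
    kept with the attendance probability. Metric values are drawn i.i.d. per
    draw from the group-shifted family (plus an optional patient-level latent
    effect). Bit-for-bit reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patients: dict[str, PatientRecord] = {}
    samples: list[SampleRecord] = []
    metric_defs = {s.name: s.definition() for s in config.metric_specs}

    dual_pending = config.include_dual_event_patient and config.n_per_group.get("grade2_4", 0) > 0
    idx = 0
    for group in GROUPS:
        for _ in range(config.n_per_group.get(group.value, 0)):
            idx += 1
            pid = f"P{idx:03d}"
            diagnosis_day = relapse_day = None
            grade = 0
            if group is OutcomeGroup.GRADE1:
                grade = 1
                diagnosis_day = _draw_day(rng, config.diagnosis_day_mean, config.diagnosis_day_sd, 7, config.follow_up_days)
            elif group is OutcomeGroup.GRADE2_4:
                grade = int(rng.integers(2, 5))
                diagnosis_day = _draw_day(rng, config.diagnosis_day_mean, config.diagnosis_day_sd, 7, config.follow_up_days)
                if dual_pending:
                    # the cohort's single dual-event patient: GVHD then relapse
                    relapse_day = _draw_day(rng, config.relapse_day_mean, config.relapse_day_sd, diagnosis_day + 1, 365)
                    dual_pending = False
            elif group is OutcomeGroup.RELAPSE:
                relapse_day = _draw_day(rng, config.relapse_day_mean, config.relapse_day_sd, 30, 365)
            patients[pid] = PatientRecord(
                patient_id=pid,
                outcome_group=group,
                gvhd_grade=grade,
                gvhd_diagnosis_day=diagnosis_day,
                relapse_day=relapse_day,
            )

            patient_effects = (
                rng.normal(0.0, config.patient_sd, len(config.metric_specs))
                if config.patient_sd > 0
                else np.zeros(len(config.metric_specs))
            )
            lo, hi = config.interval_days
            day = 0
            while True:
                day += int(rng.integers(lo, hi + 1))
                if day > config.follow_up_days:
                    break
                if rng.random() >= config.attendance:
                    continue
                metrics = {
                    spec.name: float(draw_metric_values(spec, group, 1, rng, patient_effects[j])[0])
                    for j, spec in enumerate(config.metric_specs)
                }
                samples.append(SampleRecord(patient_id=pid, day=day, metrics=metrics))

    cohort = Cohort(patients=patients, samples=samples, metric_definitions=metric_defs)
    return cohort, ground_truth_table(config)


# ---------------------------------------------------------------------------
# clone tables


@dataclass
class CloneSimConfig:
    """Multinomial clone-table generator: clone probabilities from a uniform,
    geometric(r) or symmetric Dirichlet(alpha) abundance model."""

    n_clones: int
    total_reads: int
    model: str = "uniform"  # 'uniform' | 'geometric' | 'dirichlet'
    r: float = 0.5          # geometric decay ratio
    alpha: float = 1.0      # dirichlet concentration

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.total_reads < self.n_clones:
            raise ValueError("total_reads must be >= n_clones")
        if self.model not in ("uniform", "geometric", "dirichlet"):
            raise ValueError(f"unknown abundance model {self.model!r}")
        if self.model == "geometric" and not 0.0 < self.r < 1.0:
            raise ValueError("geometric ratio r must be in (0, 1)")


def simulate_clone_table(config: CloneSimConfig, seed: int | np.random.Generator):
    """Draw a clone table; clones receiving zero reads are dropped."""
    from .diversity import CloneTable

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = config.n_clones
    if config.model == "uniform":
        probs = np.full(k, 1.0 / k)
    elif config.model == "geometric":
        probs = config.r ** np.arange(k)
        probs /= probs.sum()
    else:
        probs = rng.dirichlet(np.full(k, config.alpha))
    counts = rng.multinomial(config.total_reads, probs)
    keep = counts > 0
    ids = [f"clone_{i:05d}" for i in range(k)]
    return CloneTable(
        clone_ids=[i for i, k_ in zip(ids, keep) if k_],
        counts=counts[keep],
    )


def write_clone_table_airr(table, path) -> None:
    """Write a clone table as a minimal AIRR rearrangement TSV (one row per
    clone: v_call, junction_aa, duplicate_count) readable by read_clone_table."""
    rows = []
    for cid, count in zip(table.clone_ids, table.counts):
        rows.append({"v_call": "TRBV-sim", "junction_aa": cid, "duplicate_count": int(count)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mouse cohorts and the weight-loss GVHD score


@dataclass
class MouseSimConfig:
    """Xenotransplant-style mouse cohort: weekly blood DPT% per arm with a
    latent-normal location separation, weekly weight loss, and a lethal label
    (survival at 12 weeks)."""

    n_lethal: int = 10
    n_nonlethal: int = 10
    weeks: tuple[int, ...] = (1, 3, 6, 9, 12)
    # per-week latent shift of the lethal arm above the nonlethal arm
    dpt_shift_by_week: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 3: 1.5, 6: 2.0, 9: 2.0, 12: 2.0}
    )
    dpt_mu: float = -2.5
    dpt_sigma: float = 0.8
    # mean weekly weight-loss percent per arm (lethal mice decline steeply)
    weight_loss_slope_lethal: float = 1.6
    weight_loss_slope_nonlethal: float = 0.3
    weight_loss_sd: float = 1.5
    death_week_mean: float = 8.0
    death_week_sd: float = 2.0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        if self.n_lethal < 1 or self.n_nonlethal < 1:
            raise ValueError("both arms need at least one mouse")


def simulate_mouse_cohort(config: MouseSimConfig, seed: int | np.random.Generator) -> pd.DataFrame:
    """Per-mouse weekly series: blood DPT%, weight-loss %, 0-4 GVHD score,
    and the lethal label. Lethal mice stop contributing after their death
    week (drawn around week 8); all observations are seeded draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for arm, n in (("lethal", config.n_lethal), ("nonlethal", config.n_nonlethal)):
        for i in range(n):
            mouse_id = f"{arm}_{i:02d}"
            death_week = (
                float(np.clip(rng.normal(config.death_week_mean, config.death_week_sd), 4.0, 12.0))
                if arm == "lethal"
                else math.inf
            )
            for week in config.weeks:
                if week > death_week:
                    break
                shift = config.dpt_shift_by_week.get(week, 0.0) if arm == "lethal" else 0.0
                z = rng.normal(shift, 1.0)
                dpt = 100.0 * expit(config.dpt_mu + config.dpt_sigma * z)
                slope = (
                    config.weight_loss_slope_lethal
                    if arm == "lethal"
                    else config.weight_loss_slope_nonlethal
                )
                loss = max(0.0, rng.normal(slope * week, config.weight_loss_sd))
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "arm": arm,
                        "lethal": arm == "lethal",
                        "week": week,
                        "pct_DPT": dpt,
                        "weight_loss_pct": loss,
                        "gvhd_score": gvhd_weight_score(loss),
                    }
                )
    return pd.DataFrame(rows)


def gvhd_weight_score(pct_weight_loss: float) -> int:
    """Weight-loss component of the murine GVHD score, on the published scale:
    0 = no signs (<2% loss), 1 = 2-5%, 2 = 6-9%, 3 = 10-14%, 4 = >=15%.

    The scale is defined on integer percent bands, so non-integer inputs are
    rounded half-up to the nearest integer percent before lookup.
    """
    if pct_weight_loss < 0:
        raise ValueError(f"weight loss must be non-negative, got {pct_weight_loss}")
    pct = math.floor(pct_weight_loss + 0.5)
    if pct >= 15:
        return 4
    if pct >= 10:
        return 3
    if pct >= 6:
        return 2
    if pct >= 2:
        return 1
    return 0


# ---------------------------------------------------------------------------
# plain-text configuration round-trip (used by the CLI)


def config_to_dict(config: CohortSimConfig) -> dict:
    return {
        "n_per_group": dict(config.n_per_group),
        "interval_days": list(config.interval_days),
        "follow_up_days": config.follow_up_days,
        "attendance": config.attendance,
        "diagnosis_day_mean": config.diagnosis_day_mean,
        "diagnosis_day_sd": config.diagnosis_day_sd,
        "relapse_day_mean": config.relapse_day_mean,
        "relapse_day_sd": config.relapse_day_sd,
        "patient_sd": config.patient_sd,
        "include_dual_event_patient": config.include_dual_event_patient,
        "metrics": [
            {
                "name": s.name,
                "family": s.family,
                "mu": s.mu,
                "sigma": s.sigma,
                "shifts": dict(s.shifts),
            }
            for s in config.metric_specs
        ],
    }


def config_from_dict(data: dict) -> CohortSimConfig:
    kwargs = dict(data)
    metrics = kwargs.pop("metrics", None)
    if "interval_days" in kwargs:
        kwargs["interval_days"] = tuple(kwargs["interval_days"])
    if metrics is not None:
        kwargs["metric_specs"] = [
            MetricSimSpec(
                name=m["name"],
                family=m["family"],
                mu=float(m["mu"]),
                sigma=float(m["sigma"]),
                shifts=dict(m.get("shifts", {})),
            )
            for m in metrics
        ]
    return CohortSimConfig(**kwargs)
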