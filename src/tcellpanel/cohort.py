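"""Longitudinal allo-HCT cohort data model and I/O.

A cohort couples a patient table (outcome group, GVHD grade, event days) with
a long table of blood-draw samples, each carrying a panel of flow-derived
T cell metrics (absolute counts and percentages of CD45RO+ T cell subsets).
Samples are indexed by integer days post-transplant; analyses select either a
fixed posttransplant window or re-time each sample relative to the patient's
GVHD diagnosis day (imputing the cohort-average diagnosis day for patients
who never developed GVHD).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "OutcomeGroup",
    "MetricKind",
    "MetricScale",
    "MetricDefinition",
    "PatientRecord",
    "SampleRecord",
    "Cohort",
    "CohortError",
    "parse_cohort",
    "write_cohort",
    "select_window",
    "normalize_days",
    "fold_mfi",
]


class CohortError(ValueError):
    """Raised for malformed cohort tables or invariant violations."""


class OutcomeGroup(str, enum.Enum):
    """First reportable allo-HCT outcome, one of four mutually exclusive groups."""

    RELAPSE = "relapse"
    NO_GVHD = "no_gvhd"
    GRADE1 = "grade1"
    GRADE2_4 = "grade2_4"


class MetricKind(str, enum.Enum):
    COUNT = "count"          # cells per volume, non-negative
    FREQUENCY = "frequency"  # percent, constrained to [0, 100]


class MetricScale(str, enum.Enum):
    """Data scale of a metric; drives the screening test choice
    (linear -> Welch t test, logarithmic -> Mann-Whitney)."""

    LINEAR = "linear"
    LOGARITHMIC = "logarithmic"


@dataclass(frozen=True)
class MetricDefinition:
    name: str
    kind: MetricKind
    scale: MetricScale

    @classmethod
    def infer(cls, name: str) -> "MetricDefinition":
        """Infer a definition from the naming convention used by the tables:
        ``pct_*`` columns are frequencies on a linear percent scale, ``count_*``
        columns are cell counts treated as logarithmic."""
        if name.startswith("pct_"):
            return cls(name, MetricKind.FREQUENCY, MetricScale.LINEAR)
        if name.startswith("count_"):
            return cls(name, MetricKind.COUNT, MetricScale.LOGARITHMIC)
        # unknown prefix: safest default is a nonparametric treatment
        return cls(name, MetricKind.COUNT, MetricScale.LOGARITHMIC)


@dataclass(frozen=True)
class PatientRecord:
    """Outcome labels and event days for one allo-HCT recipient.

    ``gvhd_grade`` is the highest grade achieved in days 0-100; the group
    assignment follows the first-reportable-outcome rule, with the dual-event
    exception that grade >= 2 GVHD always places the patient in ``grade2_4``
    even if a relapse followed.
    """

    patient_id: str
    outcome_group: OutcomeGroup
    gvhd_grade: int = 0
    gvhd_diagnosis_day: int | None = None
    relapse_day: int | None = None

    def __post_init__(self) -> None:
        g = self.outcome_group
        if not 0 <= self.gvhd_grade <= 4:
            raise CohortError(f"patient {self.patient_id}: gvhd_grade {self.gvhd_grade} outside 0-4")
        if g is OutcomeGroup.NO_GVHD and self.gvhd_diagnosis_day is not None:
            raise CohortError(f"patient {self.patient_id}: no_gvhd group cannot carry a GVHD diagnosis day")
        if g in (OutcomeGroup.GRADE1, OutcomeGroup.GRADE2_4) and self.gvhd_diagnosis_day is None:
            raise CohortError(f"patient {self.patient_id}: {g.value} group requires a GVHD diagnosis day")
        if (self.gvhd_grade >= 2) != (g is OutcomeGroup.GRADE2_4):
            raise CohortError(
                f"patient {self.patient_id}: grade {self.gvhd_grade} inconsistent with group {g.value} "
                "(grade >= 2 if and only if group is grade2_4)"
            )
        if g is OutcomeGroup.GRADE1 and self.gvhd_grade != 1:
            raise CohortError(f"patient {self.patient_id}: grade1 group requires gvhd_grade 1")
        if g is OutcomeGroup.RELAPSE and self.relapse_day is None:
            raise CohortError(f"patient {self.patient_id}: relapse group requires relapse_day")
        for day_name in ("gvhd_diagnosis_day", "relapse_day"):
            day = getattr(self, day_name)
            if day is not None and day < 0:
                raise CohortError(f"patient {self.patient_id}: {day_name} must be non-negative")


@dataclass(frozen=True)
class SampleRecord:
    """One blood draw's metric panel at an integer day post-transplant.

    ``metrics`` maps metric name to value; a metric absent from the mapping is
    missing for this draw (panels run in separate tubes can fail independently)
    and is excluded pairwise by downstream analyses.
    """

    patient_id: str
    day: int
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise CohortError(f"sample ({self.patient_id}, day {self.day}): day must be non-negative")


@dataclass
class Cohort:
    patients: dict[str, PatientRecord]
    samples: list[SampleRecord]
    metric_definitions: dict[str, MetricDefinition]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.patient_id not in self.patients:
                raise CohortError(f"sample at day {s.day} references unknown patient {s.patient_id!r}")
            for name, value in s.metrics.items():
                if name not in self.metric_definitions:
                    raise CohortError(f"sample ({s.patient_id}, day {s.day}): undeclared metric {name!r}")
                defn = self.metric_definitions[name]
                if value < 0 or not math.isfinite(value):
                    raise CohortError(
                        f"metric {name!r} value {value} in sample ({s.patient_id}, day {s.day}) "
                        "must be finite and non-negative"
                    )
                if defn.kind is MetricKind.FREQUENCY and not 0.0 <= value <= 100.0:
                    raise CohortError(
                        f"frequency metric {name!r} value {value} in sample "
                        f"({s.patient_id}, day {s.day}) outside [0, 100]"
                    )

    @property
    def metric_names(self) -> list[str]:
        return list(self.metric_definitions)

    def patient_of(self, sample: SampleRecord) -> PatientRecord:
        return self.patients[sample.patient_id]


# ---------------------------------------------------------------------------
# parsing / serialization

_PATIENT_COLUMNS = ("patient_id", "outcome_group")
_OPTIONAL_PATIENT_COLUMNS = ("gvhd_grade", "gvhd_diagnosis_day", "relapse_day")


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def _optional_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return int(value)


def parse_cohort(
    samples_table,
    patients_table,
    metric_definitions: dict[str, MetricDefinition] | None = None,
) -> Cohort:
    """Parse samples and patients tables (CSV or TSV paths/buffers) into a Cohort.

    The samples table needs ``patient_id``, ``day`` and at least one metric
    column; the patients table needs ``patient_id`` and ``outcome_group`` plus
    optional ``gvhd_grade``/``gvhd_diagnosis_day``/``relapse_day``. Rows whose
    patient_id is not declared in the patients table are an error. Duplicate
    (patient_id, day) rows are merged metric-wise; a conflicting duplicate
    value for the same cell is an error.
    """
    pdf = _read_table(patients_table)
    sdf = _read_table(samples_table)

    for col in _PATIENT_COLUMNS:
        if col not in pdf.columns:
            raise CohortError(f"patients table missing required column {col!r}")
    for col in ("patient_id", "day"):
        if col not in sdf.columns:
            raise CohortError(f"samples table missing required column {col!r}")

    metric_cols = [c for c in sdf.columns if c not in ("patient_id", "day")]
    if not metric_cols:
        raise CohortError("samples table has no metric columns")
    if metric_definitions is None:
        metric_definitions = {c: MetricDefinition.infer(c) for c in metric_cols}

    patients: dict[str, PatientRecord] = {}
    for row in pdf.itertuples(index=False):
        pid = str(row.patient_id)
        if pid in patients:
            raise CohortError(f"duplicate patient_id {pid!r} in patients table")
        try:
            group = OutcomeGroup(str(row.outcome_group))
        except ValueError:
            raise CohortError(
                f"patient {pid!r}: unknown outcome_group {row.outcome_group!r}"
            ) from None
        patients[pid] = PatientRecord(
            patient_id=pid,
            outcome_group=group,
            gvhd_grade=int(getattr(row, "gvhd_grade", 0) if not pd.isna(getattr(row, "gvhd_grade", 0)) else 0),
            gvhd_diagnosis_day=_optional_int(getattr(row, "gvhd_diagnosis_day", None)),
            relapse_day=_optional_int(getattr(row, "relapse_day", None)),
        )

    merged: dict[tuple[str, int], dict[str, float]] = {}
    for i, row in enumerate(sdf.itertuples(index=False)):
        pid = str(row.patient_id)
        if pid not in patients:
            raise CohortError(f"samples table row {i}: unknown patient_id {pid!r}")
        day = int(row.day)
        cell = merged.setdefault((pid, day), {})
        for name in metric_cols:
            value = getattr(row, name)
            if pd.isna(value):
                continue
            value = float(value)
            defn = metric_definitions[name]
            if defn.kind is MetricKind.FREQUENCY and not 0.0 <= value <= 100.0:
                raise CohortError(
                    f"samples table row {i}: frequency metric {name!r} value {value} outside [0, 100]"
                )
            if name in cell and cell[name] != value:
                raise CohortError(
                    f"samples table row {i}: conflicting duplicate value for "
                    f"({pid}, day {day}, {name}): {cell[name]} vs {value}"
                )
            cell[name] = value

    samples = [
        SampleRecord(patient_id=pid, day=day, metrics=metrics)
        for (pid, day), metrics in merged.items()
    ]
    return Cohort(patients=patients, samples=samples, metric_definitions=metric_definitions)


def write_cohort(cohort: Cohort, samples_path, patients_path, sep: str = "\t") -> None:
    """Serialize a cohort back to samples/patients tables (inverse of parse_cohort)."""
    prows = []
    for p in cohort.patients.values():
        prows.append(
            {
                "patient_id": p.patient_id,
                "outcome_group": p.outcome_group.value,
                "gvhd_grade": p.gvhd_grade,
                "gvhd_diagnosis_day": p.gvhd_diagnosis_day,
                "relapse_day": p.relapse_day,
            }
        )
    pd.DataFrame(prows).to_csv(patients_path, sep=sep, index=False)

    metric_names = cohort.metric_names
    srows = []
    for s in sorted(cohort.samples, key=lambda s: (s.patient_id, s.day)):
        row: dict = {"patient_id": s.patient_id, "day": s.day}
        for name in metric_names:
            row[name] = s.metrics.get(name)
        srows.append(row)
    pd.DataFrame(srows).to_csv(samples_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# time-window selection and diagnosis-day normalization


def select_window(cohort_or_samples, day_min: int, day_max: int) -> list[SampleRecord]:
    """Samples with day in the closed interval [day_min, day_max]."""
    if day_min > day_max:
        raise ValueError(f"day_min {day_min} exceeds day_max {day_max}")
    samples = cohort_or_samples.samples if isinstance(cohort_or_samples, Cohort) else cohort_or_samples
    return [s for s in samples if day_min <= s.day <= day_max]


def normalize_days(
    cohort: Cohort,
    imputed_day: int = 54,
    day_min: int = 22,
    day_max: int = 83,
) -> list[tuple[SampleRecord, int]]:
    """Re-time samples relative to each patient's GVHD diagnosis day.

    Samples are first restricted to ``[day_min, day_max]``; each retained
    sample gets ``relative_day = day - gvhd_diagnosis_day`` when the patient
    has a diagnosis day and ``day - imputed_day`` otherwise (no-GVHD and
    relapse-only patients). The default imputed day 54 is the cohort-average
    time to GVHD diagnosis.
    """
    out = []
    for s in select_window(cohort, day_min, day_max):
        anchor = cohort.patients[s.patient_id].gvhd_diagnosis_day
        if anchor is None:
            anchor = imputed_day
        out.append((s, s.day - anchor))
    return out


def fold_mfi(marker_mfi: float, isotype_mfi: float) -> float:
    """Fold MFI: marker median fluorescence intensity over its isotype control."""
    if isotype_mfi <= 0:
        raise ValueError(f"isotype MFI must be positive, got {isotype_mfi}")
    return marker_mfi / isotype_mfi


def relabel_samples(samples: list[SampleRecord], transform) -> list[SampleRecord]:
    """Apply ``transform(metrics dict) -> metrics dict`` to every sample (helper
    for sensitivity analyses); returns new records."""
    return [replace(s, metrics=transform(dict(s.metrics))) for s in samples]
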