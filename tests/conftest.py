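import numpy as np
import pytest

from tcellpanel import (
    Cohort,
    CohortSimConfig,
    MetricDefinition,
    MetricKind,
    MetricScale,
    OutcomeGroup,
    PatientRecord,
    SampleRecord,
    simulate_cohort,
)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Hand-built 4-patient cohort (one per outcome group) with two metrics."""
    patients = {
        "A": PatientRecord("A", OutcomeGroup.NO_GVHD, 0, None, None),
        "B": PatientRecord("B", OutcomeGroup.GRADE1, 1, 40, None),
        "C": PatientRecord("C", OutcomeGroup.GRADE2_4, 3, 30, None),
        "D": PatientRecord("D", OutcomeGroup.RELAPSE, 0, None, 120),
    }
    defs = {
        "pct_DPT": MetricDefinition("pct_DPT", MetricKind.FREQUENCY, MetricScale.LINEAR),
        "count_CD45RO": MetricDefinition("count_CD45RO", MetricKind.COUNT, MetricScale.LOGARITHMIC),
    }
    samples = [
        SampleRecord("A", 7, {"pct_DPT": 1.0, "count_CD45RO": 800.0}),
        SampleRecord("A", 12, {"pct_DPT": 1.5, "count_CD45RO": 650.0}),
        SampleRecord("B", 10, {"pct_DPT": 4.0, "count_CD45RO": 500.0}),
        SampleRecord("B", 50, {"pct_DPT": 5.5, "count_CD45RO": 430.0}),
        SampleRecord("C", 9, {"pct_DPT": 8.0, "count_CD45RO": 300.0}),
        SampleRecord("C", 17, {"pct_DPT": 6.5, "count_CD45RO": 350.0}),
        SampleRecord("D", 14, {"pct_DPT": 0.4, "count_CD45RO": 120.0}),
        SampleRecord("D", 60, {"pct_DPT": 0.6, "count_CD45RO": 90.0}),
    ]
    return Cohort(patients=patients, samples=samples, metric_definitions=defs)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated cohort shared across tests (seeded)."""
    return simulate_cohort(CohortSimConfig(), seed=20260920)


def pair_count_auc(values, labels) -> float:
    """Exhaustive positive-negative pair counting oracle (ties scored 0.5)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
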