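import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellpanel import (
    CombinedScoreModel,
    DEFAULT_CONTRASTS,
    Direction,
    DirectedECDF,
    LabeledValues,
    MetricDefinition,
    MetricKind,
    MetricScale,
    OutcomeGroup,
    PanelModel,
    PatientRecord,
    SampleRecord,
    Cohort,
    directed_value,
    fit_directed_ecdf,
    loocv_combined_auc,
    mid_rank_ecdf,
    panel_score,
    select_window,
)


def lv_of(values, labels, units=None):
    values = np.asarray(values, float)
    if units is None:
        units = np.arange(len(values)).astype(object)
    return LabeledValues(values, np.asarray(labels), np.asarray(units, dtype=object))


class TestMidRankECDF:
    def test_mid_rank_at_tie(self):
        assert mid_rank_ecdf([1, 2, 3, 4], 2) == pytest.approx(0.375)

    def test_clamp_above_support(self):
        assert mid_rank_ecdf([1, 2, 3, 4], 5) == pytest.approx(0.875)  # 1 - 1/(2*4)

    def test_clamp_below_support(self):
        assert mid_rank_ecdf([1, 2, 3, 4], 0) == pytest.approx(0.125)

    def test_single_training_point(self):
        assert mid_rank_ecdf([7.0], 7.0) == pytest.approx(0.5)

    def test_empty_training_set_is_error(self):
        with pytest.raises(ValueError):
            mid_rank_ecdf([], 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        train=st.lists(st.integers(-5, 5), min_size=1, max_size=30),
        x=st.integers(-7, 7),
    )
    def test_bounds_and_brute_force(self, train, x):
        n = len(train)
        e = mid_rank_ecdf(train, x)
        raw = (sum(v < x for v in train) + 0.5 * sum(v == x for v in train)) / n
        assert e == pytest.approx(min(max(raw, 1 / (2 * n)), 1 - 1 / (2 * n)), abs=1e-15)
        assert 0.0 < e < 1.0


class TestDirectedECDF:
    def test_perfect_separation_higher(self):
        m = fit_directed_ecdf(lv_of([1, 2, 3, 4], [0, 0, 1, 1]), "m")
        assert m.direction is Direction.HIGHER_IS_POSITIVE
        assert m.train_auc == 1.0

    def test_negation_flips_direction(self):
        m = fit_directed_ecdf(lv_of([-1, -2, -3, -4], [0, 0, 1, 1]), "m")
        assert m.direction is Direction.LOWER_IS_POSITIVE
        assert m.train_auc == 1.0

    def test_exact_tie_breaks_higher(self):
        m = fit_directed_ecdf(lv_of([1, 2, 1, 2], [0, 0, 1, 1]), "m")
        assert m.train_auc == 0.5
        assert m.direction is Direction.HIGHER_IS_POSITIVE

    def test_directed_value_complement(self):
        train = np.array([1.0, 2.0, 3.0, 4.0])
        hi = DirectedECDF("m", train, Direction.HIGHER_IS_POSITIVE, 0.6)
        lo = DirectedECDF("m", train, Direction.LOWER_IS_POSITIVE, 0.6)
        for x in (-1.0, 2.0, 2.5, 9.0):
            assert directed_value(hi, x) + directed_value(lo, x) == pytest.approx(1.0, abs=1e-15)
        assert directed_value(hi, 2.0) == pytest.approx(0.375)
        assert directed_value(lo, 2.0) == pytest.approx(0.625)


class TestPanelScore:
    def test_single_metric_panel_is_directed_value(self):
        comp = fit_directed_ecdf(lv_of([1, 2, 3, 4], [0, 0, 1, 1]), "m")
        panel = PanelModel([comp])
        assert panel_score(panel, {"m": 2.0}) == pytest.approx(directed_value(comp, 2.0))

    def test_product_of_components(self):
        # symmetric single-point trainings give factor 0.5 each
        a = DirectedECDF("a", np.array([1.0]), Direction.HIGHER_IS_POSITIVE, 0.5)
        b = DirectedECDF("b", np.array([1.0]), Direction.HIGHER_IS_POSITIVE, 0.5)
        assert panel_score(PanelModel([a, b]), {"a": 1.0, "b": 1.0}) == pytest.approx(0.25)

    def test_missing_metric_is_error(self):
        comp = fit_directed_ecdf(lv_of([1, 2, 3, 4], [0, 0, 1, 1]), "m")
        with pytest.raises(KeyError, match="m"):
            panel_score(PanelModel([comp]), {"other": 1.0})

    def test_monotone_in_higher_metric(self):
        comp = fit_directed_ecdf(lv_of(np.arange(20.0), np.r_[np.zeros(10), np.ones(10)].astype(int)), "m")
        panel = PanelModel([comp])
        scores = [panel_score(panel, {"m": x}) for x in np.linspace(-5, 25, 40)]
        assert (np.diff(scores) >= -1e-15).all()


def _grid_cohort(values_by_patient, groups, metric="pct_DPT"):
    """Cohort with one sample per patient, a single frequency metric."""
    patients, samples = {}, []
    for pid, (value, group) in enumerate(zip(values_by_patient, groups)):
        name = f"P{pid}"
        kwargs = {}
        if group is OutcomeGroup.GRADE2_4:
            kwargs = dict(gvhd_grade=2, gvhd_diagnosis_day=40)
        elif group is OutcomeGroup.GRADE1:
            kwargs = dict(gvhd_grade=1, gvhd_diagnosis_day=40)
        elif group is OutcomeGroup.RELAPSE:
            kwargs = dict(relapse_day=150)
        patients[name] = PatientRecord(name, group, **kwargs)
        samples.append(SampleRecord(name, 10, {metric: float(value)}))
    defs = {metric: MetricDefinition(metric, MetricKind.FREQUENCY, MetricScale.LINEAR)}
    return Cohort(patients=patients, samples=samples, metric_definitions=defs)


class TestLOOCV:
    def test_wide_margin_separation_gives_auc_one(self):
        groups = [OutcomeGroup.NO_GVHD] * 4 + [OutcomeGroup.GRADE2_4] * 4
        cohort = _grid_cohort([1, 2, 3, 4, 50, 60, 70, 80], groups)
        cv = loocv_combined_auc(
            cohort, cohort.samples, ["pct_DPT"], DEFAULT_CONTRASTS["grade2plus"], unit="patient"
        )
        assert cv.auc == 1.0
        assert cv.n_units == 8
        assert len(cv.held_out) == 8

    def test_sample_unit_equals_patient_unit_with_one_sample_each(self):
        groups = [OutcomeGroup.NO_GVHD] * 4 + [OutcomeGroup.GRADE2_4] * 4
        cohort = _grid_cohort([3, 9, 1, 7, 50, 2, 70, 8], groups)
        kw = dict(metrics=["pct_DPT"], contrast=DEFAULT_CONTRASTS["grade2plus"])
        cv_p = loocv_combined_auc(cohort, cohort.samples, unit="patient", **kw)
        cv_s = loocv_combined_auc(cohort, cohort.samples, unit="sample", **kw)
        assert cv_p.auc == pytest.approx(cv_s.auc, abs=1e-15)
        assert sorted(cv_p.held_out["score"]) == pytest.approx(sorted(cv_s.held_out["score"]))

    def test_too_few_units_per_class_is_error(self):
        groups = [OutcomeGroup.NO_GVHD] * 5 + [OutcomeGroup.GRADE2_4]
        cohort = _grid_cohort([1, 2, 3, 4, 5, 9], groups)
        with pytest.raises(ValueError, match="2 units per class"):
            loocv_combined_auc(cohort, cohort.samples, ["pct_DPT"], DEFAULT_CONTRASTS["grade2plus"])

    def test_every_unit_scored_exactly_once(self, default_sim):
        cohort, _ = default_sim
        window = select_window(cohort, 7, 17)
        cv = loocv_combined_auc(
            cohort, window, ["pct_DPT", "pct_Treg"], DEFAULT_CONTRASTS["any_gvhd"]
        )
        per_unit = cv.held_out.groupby("unit_id").size()
        lv_counts = {}
        for s in window:
            g = cohort.patients[s.patient_id].outcome_group
            if DEFAULT_CONTRASTS["any_gvhd"].label_of(g) is not None:
                lv_counts[s.patient_id] = lv_counts.get(s.patient_id, 0) + 1
        assert dict(per_unit) == lv_counts

    def test_flip_covariance_leaves_scores_identical(self, default_sim):
        """Reversing one metric's order (a strictly decreasing transform)
        flips its fitted direction per fold but leaves the combined scores
        unchanged: the mid-rank ECDF complements exactly."""
        cohort, _ = default_sim
        window = select_window(cohort, 7, 17)
        contrast = DEFAULT_CONTRASTS["grade2plus"]
        base = loocv_combined_auc(cohort, window, ["pct_DPT", "count_CD45RO"], contrast,
                                  keep_fold_models=True)

        flipped_samples = [
            SampleRecord(
                s.patient_id, s.day,
                {**s.metrics, "count_CD45RO": 1e6 / (1.0 + s.metrics["count_CD45RO"])},
            )
            for s in window
        ]
        defs = dict(cohort.metric_definitions)
        defs["count_CD45RO"] = MetricDefinition("count_CD45RO", MetricKind.COUNT, MetricScale.LOGARITHMIC)
        flipped = Cohort(patients=cohort.patients, samples=flipped_samples, metric_definitions=defs)
        res = loocv_combined_auc(flipped, flipped.samples, ["pct_DPT", "count_CD45RO"], contrast,
                                 keep_fold_models=True)
        assert res.auc == pytest.approx(base.auc, abs=1e-12)
        for u, panel in base.fold_models.items():
            d0 = panel.components[1].direction
            d1 = res.fold_models[u].components[1].direction
            assert d0 is not d1

    def test_model_shortcut(self, default_sim):
        cohort, _ = default_sim
        window = select_window(cohort, 7, 17)
        model = CombinedScoreModel(cohort, ["pct_DPT", "pct_Treg"], DEFAULT_CONTRASTS["grade2plus"], window)
        res = model.fit()
        assert set(res.component_table().columns) == {"metric", "direction", "train_auc"}
        assert (res.component_table()["train_auc"] >= 0.5).all()
        assert "Combined ECDF-product score" in res.summary()
        cv = model.loocv(unit="patient")
        assert 0.0 <= cv.auc <= 1.0
        assert "LOOCV AUC" in cv.summary()
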