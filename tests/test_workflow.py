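"""Three-block screening cascade: training, thresholds, stage 2, dosing."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import honeyscreen as hs
from honeyscreen.preprocess import assemble_matrix
from honeyscreen.synth import SampleRecipe, make_honey_sample
from honeyscreen.workflow import (
    ScreeningDecision,
    WorkflowModels,
    _stage1_class,
    classify_stage1,
    classify_stage2,
    quantify,
    report,
    screen,
    summarize_report,
    to_mg_per_packet,
    train_workflow,
)


def sample_bins(recipe, acq, seed=0):
    s, _ = make_honey_sample(recipe, acq, seed=seed)
    return assemble_matrix([s]).values[0]


class TestTraining:
    def test_model_shapes(self, models):
        assert models.plsda_I.T.shape == (34, 3)
        assert models.plsda_II.T.shape == (24, 3)  # T/S rows only
        assert models.n_train_II == 24
        assert models.pls_IV.T.shape[0] == 40  # tadalafil calibration
        assert models.pls_III.T.shape[0] == 15  # sildenafil calibration

    def test_missing_class_rejected(self, training, calib_tadalafil, calib_sildenafil):
        _, matrix, labels = training
        bad = ["T" if l == "N" else l for l in labels]
        with pytest.raises(ValueError, match="missing class"):
            train_workflow(matrix, bad, calib_tadalafil, calib_sildenafil)

    def test_empty_calibration_rejected(self, training, calib_tadalafil):
        _, matrix, labels = training
        empty = replace(
            calib_tadalafil[0], sample_ids=[], values=np.empty((0, 320)), meta=[]
        )
        with pytest.raises(ValueError, match="empty"):
            train_workflow(matrix, labels, calib_tadalafil, (empty, np.array([])))

    def test_serialization_round_trip(self, models, tmp_path):
        p = tmp_path / "models.json"
        models.to_json(p)
        back = WorkflowModels.from_json(p)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, models.bin_centers.size))
        from honeyscreen.chemometrics import predict_y

        assert np.allclose(
            predict_y(models.plsda_I, X), predict_y(back.plsda_I, X)
        )
        assert np.allclose(models.centroid_S, back.centroid_S)


class TestStage1:
    @pytest.mark.parametrize(
        "y,expected",
        [
            (0.20, "non-adulterated"),
            (0.299, "non-adulterated"),
            (0.30, "borderline"),
            (0.47, "borderline"),
            (0.50, "borderline"),
            (0.58, "adulterated"),
            (1.08, "adulterated"),
            (2.21, "adulterated"),
        ],
    )
    def test_threshold_rule(self, y, expected):
        assert _stage1_class(y, (0.30, 0.50)) == expected

    def test_blank_classified_non_adulterated(self, models, acq, base_confusers):
        r = SampleRecipe(adulterant="none", confusers=base_confusers)
        y, cls = classify_stage1(models, sample_bins(r, acq, seed=5))
        assert cls == "non-adulterated" and y < 0.30

    def test_adulterated_sample_flagged(self, models, acq, base_confusers):
        conf = dict(base_confusers, formulation=0.65)
        r = SampleRecipe(
            adulterant="tadalafil", dose_mg_per_packet=40, confusers=conf
        )
        y, cls = classify_stage1(models, sample_bins(r, acq, seed=5))
        assert cls == "adulterated" and y > 0.50


class TestStage2:
    def test_tadalafil_sample_assigned_t(self, models, acq, base_confusers):
        conf = dict(base_confusers, formulation=0.65)
        r = SampleRecipe(adulterant="tadalafil", dose_mg_per_packet=40, confusers=conf)
        assignment, t2, scores = classify_stage2(models, sample_bins(r, acq, seed=6))
        assert assignment == "tadalafil"
        assert scores.shape == (3,)

    def test_sildenafil_sample_assigned_s(self, models, acq, base_confusers):
        conf = dict(base_confusers, formulation=0.65)
        r = SampleRecipe(adulterant="sildenafil", dose_mg_per_packet=120, confusers=conf)
        assignment, _, _ = classify_stage2(models, sample_bins(r, acq, seed=6))
        assert assignment == "sildenafil"

    def test_benzoate_dominated_sample_is_outlier(self, models, acq, base_confusers):
        conf = dict(base_confusers, benzoate=1.0)
        r = SampleRecipe(adulterant="none", confusers=conf)
        assignment, t2, _ = classify_stage2(models, sample_bins(r, acq, seed=6))
        assert assignment == "outlier"
        from honeyscreen.chemometrics import hotelling_limit

        assert t2 > hotelling_limit(models.n_train_II, 3)

    def test_cascade_contract(self, models):
        with pytest.raises(ValueError, match="stage 2"):
            classify_stage2(
                models, np.zeros(models.bin_centers.size), stage1="non-adulterated"
            )

    def test_equidistant_tie_breaks_to_tadalafil(self, models):
        from copy import deepcopy

        m = deepcopy(models)
        # centroids placed symmetrically: the training mean (scores at the
        # origin) is exactly equidistant
        m.centroid_T = np.array([1.0, 0.0, 0.0])
        m.centroid_S = np.array([-1.0, 0.0, 0.0])
        mean_row = m.plsda_II.scaling.inverse(np.zeros((1, m.bin_centers.size)))[0]
        assignment, _, _ = classify_stage2(m, mean_row)
        assert assignment == "tadalafil"


class TestQuantification:
    def test_noise_free_training_point_recovery(self, models_noise_free, acq_nf):
        s = hs.render_spectrum({"tadalafil": 5.0, "TSP": 500.0}, acq_nf, seed=0)
        bins = assemble_matrix([s]).values[0]
        c, floored = quantify(models_noise_free, bins, "tadalafil")
        assert not floored
        assert c == pytest.approx(5.0, abs=1e-3)

    def test_blank_predicts_near_zero(self, models, acq):
        preds = []
        for seed in range(10):
            s = hs.render_spectrum({"TSP": 500.0}, acq, seed=seed)
            bins = assemble_matrix([s]).values[0]
            c, _ = quantify(models, bins, "tadalafil")
            preds.append(c)
        # well below the lowest calibration level
        assert np.mean(preds) < 0.1

    def test_unknown_adulterant_rejected(self, models):
        with pytest.raises(ValueError, match="unknown adulterant"):
            quantify(models, np.zeros(models.bin_centers.size), "caffeine")

    def test_negative_prediction_floored(self, models):
        # an extreme negative fingerprint forces a negative raw prediction
        bins = np.full(models.bin_centers.size, -10.0)
        c, floored = quantify(models, bins, "tadalafil")
        assert c == 0.0 and floored


class TestDoseConversion:
    def test_worked_example(self):
        q = to_mg_per_packet(C_A=1.0, V=2.0, m_packet=10.0, m=1.0)
        assert q.Q == pytest.approx(20.0)

    def test_zero_concentration(self):
        assert to_mg_per_packet(0.0, 2.0, 10.0, 1.0).Q == 0.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            to_mg_per_packet(1.0, 2.0, 10.0, 0.0)


class TestScreen:
    def test_blanks_stop_at_stage1(self, models, acq):
        cohort = hs.test_cohort(acq, seed=41)
        decisions = screen(models, cohort.spectra)
        by_id = {d.sample_id: d for d in decisions}
        for sid, row in cohort.truth.iterrows():
            if row["adulterant"] == "none":
                assert by_id[sid].stage1 == "non-adulterated"
                assert by_id[sid].stage2 == "not-evaluated"
                assert by_id[sid].dose_mg_per_packet is None

    def test_replicates_averaged_with_sd(self, models, acq):
        cohort = hs.test_cohort(acq, seed=42, replicates=2)
        decisions = screen(models, cohort.spectra)
        assert len(decisions) == cohort.n_samples
        quantified = [d for d in decisions if d.dose_mg_per_packet is not None]
        assert quantified and all(d.dose_sd is not None for d in quantified)

    def test_empty_input(self, models):
        assert screen(models, []) == []

    def test_cascade_ordering_invariant(self, models, acq):
        cohort = hs.test_cohort(acq, seed=43)
        for d in screen(models, cohort.spectra):
            if d.stage2 != "not-evaluated":
                assert d.stage1 in ("adulterated", "borderline")
            if d.dose_mg_per_packet is not None:
                assert d.stage2 in ("tadalafil", "sildenafil")


class TestReport:
    def test_report_columns_and_reference_deviation(self, models, acq):
        cohort = hs.test_cohort(acq, seed=44)
        decisions = screen(models, cohort.spectra)
        table = report(decisions, reference=cohort.truth)
        assert list(table.columns[:4]) == ["sample_id", "ypredps", "stage1", "stage2"]
        dev = table["pct_dev"].dropna()
        assert len(dev) > 0 and dev.abs().median() < 10.0

    def test_empty_report(self):
        table = report([])
        assert len(table) == 0 and "ypredps" in table.columns

    def test_summary_counts(self):
        decisions = [
            ScreeningDecision("a", 0.2, "non-adulterated"),
            ScreeningDecision("b", 0.9, "adulterated", "tadalafil",
                              dose_mg_per_packet=30.0, dose_sd=1.0),
            ScreeningDecision("c", 0.7, "adulterated", "sildenafil",
                              dose_mg_per_packet=60.0, dose_sd=2.0),
        ]
        ref = pd.DataFrame(
            {"adulterant": ["none", "tadalafil", "tadalafil"],
             "dose_mg_per_packet": [0.0, 30.0, 55.0]},
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        summary = summarize_report(report(decisions, reference=ref))
        assert summary["n_tadalafil_assigned"] == 1
        assert summary["n_sildenafil_assigned"] == 1
        assert summary["n_non_adulterated"] == 1
        assert summary["n_disagreements"] == 1  # c: reference says tadalafil
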