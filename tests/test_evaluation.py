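"""Fold plans, metric arithmetic, CV harness, ablation and pipeline comparison."""

import numpy as np
import pytest

import ramanpipe as rp
from ramanpipe import ModelSpec
from ramanpipe.evaluation import (
    AblationReport,
    confusion_and_metrics,
    grouped_kfold_splits,
    lopo_splits,
    run_cv_experiment,
)


def make_cohort(spectra_per_patient, n_points=40, seed=0):
    """Hand-built cohort with given per-patient spectrum counts (balanced labels)."""
    rng = np.random.default_rng(seed)
    grid = rp.SpectralGrid(np.arange(500.0, 500.0 + n_points))
    records = []
    for pi, n in enumerate(spectra_per_patient):
        for si in range(n):
            records.append(rp.SpectrumRecord(
                f"p{pi}s{si}", f"p{pi}", si % 2, rng.random(n_points)))
    return rp.Cohort(grid, records)


class TestFoldPlans:
    def test_lopo_one_fold_per_patient(self, default_cohort):
        plan = lopo_splits(default_cohort)
        assert len(plan) == 22
        plan.validate(default_cohort)

    def test_lopo_validation_sizes_follow_patients(self):
        cohort = make_cohort([2, 3, 4])
        plan = lopo_splits(cohort)
        assert sorted(len(v) for _, v in plan.folds) == [2, 3, 4]

    def test_lopo_partitions_cohort(self):
        cohort = make_cohort([4, 4, 6, 2])
        plan = lopo_splits(cohort)
        seen = [s for _, val in plan.folds for s in val]
        assert sorted(seen) == sorted(cohort.spectrum_ids)

    def test_lopo_single_patient_rejected(self):
        with pytest.raises(ValueError):
            lopo_splits(make_cohort([5]))

    def test_grouped_kfold_properties(self, default_cohort):
        plan = grouped_kfold_splits(default_cohort, k=10, seed=0)
        assert len(plan) == 10
        plan.validate(default_cohort)  # partition + patient-disjoint
        patient_of = {r.spectrum_id: r.patient_id for r in default_cohort.records}
        for train_ids, val_ids in plan.folds:
            assert not {patient_of[s] for s in train_ids} & {patient_of[s] for s in val_ids}

    def test_grouped_kfold_k_exceeding_patients_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold_splits(make_cohort([2, 2, 2]), k=4)


class TestMetrics:
    def test_perfect_predictions(self):
        y = [0] * 10 + [1] * 10
        cm, rep = confusion_and_metrics(y, y)
        assert cm.counts[0, 1] == cm.counts[1, 0] == 0
        assert rep.accuracy == 100.0
        assert rep.precision == rep.recall == (100.0, 100.0)

    def test_reference_cnn_row_reconstruction(self):
        """Counts [[194,27],[11,210]] reproduce the reference per-class metrics."""
        truth = [0] * 221 + [1] * 221
        preds = [0] * 194 + [1] * 27 + [0] * 11 + [1] * 210
        cm, rep = confusion_and_metrics(truth, preds)
        np.testing.assert_array_equal(cm.counts, [[194, 27], [11, 210]])
        assert round(rep.accuracy, 1) == 91.4
        assert tuple(round(r, 1) for r in rep.recall) == (87.8, 95.0)
        assert tuple(round(p, 1) for p in rep.precision) == (94.6, 88.6)
        assert tuple(round(f, 1) for f in rep.f1) == (91.1, 91.7)

    def test_f1_is_harmonic_mean_of_reference_pair(self):
        f1 = 2 * 94.6 * 87.8 / (94.6 + 87.8)
        assert round(f1, 1) == 91.1

    def test_agrees_with_sklearn_on_random_labels(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            _, rep = confusion_and_metrics(y, p)
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, labels=[0, 1], zero_division=0)
            np.testing.assert_allclose(rep.precision, 100 * prec, atol=1e-9)
            np.testing.assert_allclose(rep.recall, 100 * rec, atol=1e-9)
            np.testing.assert_allclose(rep.f1, 100 * f1, atol=1e-9)

    def test_balanced_accuracy_equals_mean_recall(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 50)
        p = rng.integers(0, 2, 100)
        _, rep = confusion_and_metrics(y, p)
        assert rep.accuracy == pytest.approx((rep.recall[0] + rep.recall[1]) / 2)

    def test_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_and_metrics([0, 1], [0])
        with pytest.raises(ValueError, match="label"):
            confusion_and_metrics([0, 2], [0, 1])


class TestCVExperiment:
    @pytest.fixture(scope="class")
    def separated_cohort(self):
        """Small low-noise cohort for the sentinel / error-context checks."""
        cfg = rp.SimulatorConfig(n_patients=8, spectra_per_patient_per_class=6,
                                 extra_pairs_first_patient=0, noise_sd=0.01,
                                 patient_effect_sd=0.05, seed=2)
        grid = rp.SpectralGrid(np.arange(500.0, 3200.0, 2.0))
        return rp.generate_cohort(cfg, grid=grid)

    @pytest.fixture(scope="class")
    def low_noise_cohort(self):
        """Full-size study cohort under quiet acquisition conditions."""
        cfg = rp.SimulatorConfig(noise_sd=0.01, patient_effect_sd=0.05, seed=2)
        return rp.generate_cohort(cfg)

    def test_separable_cohort_high_accuracy(self, low_noise_cohort):
        plan = lopo_splits(low_noise_cohort)
        res = run_cv_experiment(
            low_noise_cohort, "suggested_ml", ModelSpec("xgboost", seed=0), plan)
        assert res.metrics.accuracy >= 95.0
        assert res.confusion.total == len(low_noise_cohort)

    def test_permuted_labels_fall_to_chance(self, low_noise_cohort):
        rng = np.random.default_rng(5)
        permuted = rng.permutation(low_noise_cohort.labels)
        plan = lopo_splits(low_noise_cohort)
        res = run_cv_experiment(
            low_noise_cohort, "suggested_ml", ModelSpec("xgboost", seed=0), plan,
            labels=permuted)
        assert 40.0 <= res.metrics.accuracy <= 60.0

    def test_patient_hash_sentinel_gains_nothing(self, separated_cohort):
        """A patient-identifying feature cannot lift grouped-CV accuracy when
        labels are randomized within patients."""
        cohort = separated_cohort
        rng = np.random.default_rng(31)
        # labels random within patient: any real signal is destroyed, but a
        # spectrum-level split could still memorize patient -> label
        by_patient = {}
        labels = cohort.labels.copy()
        for i, pid in enumerate(cohort.patient_ids):
            by_patient.setdefault(pid, []).append(i)
        for idxs in by_patient.values():
            labels[idxs] = rng.permutation(labels[idxs])
        # append the sentinel column: a patient-id hash
        X = cohort.matrix
        sentinel = np.array([hash(p) % 1000 for p in cohort.patient_ids], dtype=float)
        aug = np.hstack([X, sentinel[:, None]])
        grid = rp.SpectralGrid(np.append(cohort.grid.shifts, 9000.0))
        records = [
            rp.SpectrumRecord(r.spectrum_id, r.patient_id, r.label, aug[i])
            for i, r in enumerate(cohort.records)
        ]
        aug_cohort = rp.Cohort(grid, records)
        plan = grouped_kfold_splits(aug_cohort, k=4, seed=1)
        spec = rp.PipelineSpec("raw_full", (), region="full")
        res = run_cv_experiment(aug_cohort, spec, ModelSpec("xgboost", seed=0), plan,
                                labels=labels)
        assert 35.0 <= res.metrics.accuracy <= 65.0

    def test_class_swapped_labels_mirror_accuracy(self, separated_cohort):
        """Training on complemented labels yields complementary predictions:
        scored against the original labels, accuracy flips to ~(100 - acc)."""
        plan = lopo_splits(separated_cohort)
        model = ModelSpec("xgboost", seed=0)
        res = run_cv_experiment(separated_cohort, "suggested_ml", model, plan)
        swapped = run_cv_experiment(separated_cohort, "suggested_ml", model, plan,
                                    labels=1 - separated_cohort.labels)
        order = separated_cohort.spectrum_ids
        y = separated_cohort.labels
        acc_vs_original = 100.0 * np.mean(
            [swapped.predictions[s] for s in order] == y)
        assert acc_vs_original == pytest.approx(100.0 - res.metrics.accuracy, abs=10.0)

    def test_fold_errors_carry_context(self, separated_cohort):
        plan = lopo_splits(separated_cohort)
        bad = rp.PipelineSpec(
            "bad", (rp.StageSpec("pca", {"n_components": 10_000}),), region="full")
        with pytest.raises(RuntimeError, match="fold 0"):
            run_cv_experiment(separated_cohort, bad, ModelSpec("xgboost"), plan)


class TestAblation:
    def test_telescoping_total(self):
        rep = AblationReport(
            stages=["raw", "baseline_correction", "l2_normalization", "median_filter", "pca"],
            accuracy=[71.2, 76.2, 82.4, 84.4, 87.3],
            recall=[70.0, 75.5, 81.0, 83.0, 86.6],
        )
        assert rep.total_accuracy_improvement == pytest.approx(sum(rep.accuracy_deltas))
        assert rep.total_accuracy_improvement == pytest.approx(rep.accuracy[-1] - rep.accuracy[0])

    def test_reference_step_gains_sum_to_total(self):
        """The reference per-step accuracy gains are mutually consistent."""
        deltas = [5.0, 6.2, 2.0, 2.9]
        start = 71.2
        rep = AblationReport(
            stages=["raw", "baseline_correction", "l2_normalization", "median_filter", "pca"],
            accuracy=np.cumsum([start] + deltas).tolist(),
            recall=np.cumsum([start] + deltas).tolist(),
        )
        assert round(rep.total_accuracy_improvement, 1) == 16.1
        np.testing.assert_allclose(rep.accuracy_deltas, deltas, atol=1e-9)

    def test_ablation_harness_stage_labels(self, small_cohort):
        plan = grouped_kfold_splits(small_cohort, k=4, seed=0)
        rep = rp.run_ablation(
            small_cohort, ModelSpec("xgboost", seed=0, hyperparams={"n_estimators": 50}),
            plan, pca_components=10)
        assert rep.stages == [
            "raw", "baseline_correction", "l2_normalization", "median_filter", "pca"]
        assert len(rep.accuracy) == 5
        assert rep.total_accuracy_improvement == pytest.approx(sum(rep.accuracy_deltas))


class TestComparePipelines:
    def test_four_presets_reported_and_deterministic(self, small_cohort):
        plan = grouped_kfold_splits(small_cohort, k=4, seed=0)
        model = ModelSpec("xgboost", seed=0, hyperparams={"n_estimators": 50})
        table = rp.compare_pipelines(small_cohort, model, plan)
        assert set(table) == {"pipeline_a", "pipeline_b", "pipeline_c", "suggested_ml"}
        again = rp.compare_pipelines(small_cohort, model, plan, ["suggested_ml"])
        assert again["suggested_ml"].metrics == table["suggested_ml"].metrics
        for res in table.values():
            r = res.metrics.rounded()
            assert set(r["per_class"]["healthy"]) == {"precision", "recall", "f1"}
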