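"""Fold combinatorics and isolation, metric oracles (concordant pairs,
Clopper-Pearson, DeLong), ensembling, confusion matrices and the baseline."""

import numpy as np
import pytest
from scipy.stats import binom

from auscult.audio_io import DIAGNOSES, PatientRecord
from auscult.evaluation import (
    baseline_predict,
    clopper_pearson,
    confidence_intervals,
    confusion_matrix,
    delong_auroc,
    ensemble_predict,
    evaluate_binary,
    fit_baseline,
    make_nested_folds,
)


def fake_patients(n_per_class=12):
    patients = []
    i = 0
    for d in DIAGNOSES:
        for _ in range(n_per_class):
            patients.append(
                PatientRecord(f"p{i}", d, "centre_a", age=5.0, respiratory_rate=30.0)
            )
            i += 1
    return patients


class TestNestedFolds:
    def test_k5_gives_20_splits(self):
        plan = make_nested_folds(fake_patients(), k=5, rng=0)
        assert len(plan.splits) == 20

    def test_k3_gives_6_splits(self):
        plan = make_nested_folds(fake_patients(), k=3, rng=0)
        assert len(plan.splits) == 6

    def test_fold_isolation_every_split(self):
        patients = fake_patients()
        plan = make_nested_folds(patients, k=5, rng=1)
        all_ids = {p.patient_id for p in patients}
        for s in range(len(plan.splits)):
            train, tune, test = plan.split_patients(patients, s)
            train_ids = {p.patient_id for p in train}
            tune_ids = {p.patient_id for p in tune}
            test_ids = {p.patient_id for p in test}
            assert not (train_ids | tune_ids) & test_ids
            assert not train_ids & tune_ids
            assert train_ids | tune_ids | test_ids == all_ids

    def test_stratification_within_one_patient(self):
        patients = fake_patients(n_per_class=11)  # not divisible by 5
        plan = make_nested_folds(patients, k=5, rng=2)
        diag = {p.patient_id: p.diagnosis for p in patients}
        for fold in plan.folds:
            for d in DIAGNOSES:
                count = sum(diag[pid] == d for pid in fold)
                assert abs(count - 11 / 5) <= 1.0

    def test_json_round_trip(self, tmp_path):
        plan = make_nested_folds(fake_patients(), k=5, rng=3)
        plan.to_json(tmp_path / "plan.json")
        from auscult.evaluation import FoldPlan

        back = FoldPlan.from_json(tmp_path / "plan.json")
        assert back.k == plan.k
        assert back.folds == plan.folds
        assert back.splits == plan.splits

    def test_small_class_rejected(self):
        patients = fake_patients(n_per_class=3)
        with pytest.raises(ValueError, match="fewer than"):
            make_nested_folds(patients, k=5, rng=0)


class TestEvaluateBinary:
    def test_perfect_case(self):
        m = evaluate_binary([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
        assert (m.sensitivity, m.specificity, m.auroc) == (1.0, 1.0, 1.0)

    def test_auroc_is_concordant_pair_fraction(self):
        m = evaluate_binary([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert m.auroc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_label_flip_symmetry(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 40)
        a = evaluate_binary(scores, labels).auroc
        b = evaluate_binary(scores, 1 - labels).auroc
        assert a == pytest.approx(1.0 - b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_binary([0.5, 0.6], [1, 1])

    @pytest.mark.parametrize("trial", range(20))
    def test_auroc_matches_brute_force_pair_counting(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        expected = wins / (len(pos) * len(neg))
        assert evaluate_binary(scores, labels).auroc == pytest.approx(expected, abs=1e-12)


class TestClopperPearson:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = clopper_pearson(0, 20)
        assert lo == 0.0
        assert 0 < hi < 0.2

    def test_all_successes_closed_form(self):
        # lower bound of the exact interval at 10/10: (alpha/2)^(1/n)
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-10)

    def test_coverage_at_n30_p07(self):
        # empirical coverage of the exact interval is at least nominal
        n, p, reps = 30, 0.7, 10_000
        rng = np.random.default_rng(0)
        ks = rng.binomial(n, p, size=reps)
        bounds = {k: clopper_pearson(int(k), n) for k in np.unique(ks)}
        covered = np.array([bounds[k][0] <= p <= bounds[k][1] for k in ks])
        assert covered.mean() >= 0.95

    def test_interval_brackets_point_estimate(self):
        for k, n in [(3, 17), (11, 13), (1, 2)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi


class TestDeLong:
    def test_point_estimate_equals_rank_auroc(self):
        from sklearn.metrics import roc_auc_score

        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[:2] = [0, 1]
            auc, _ = delong_auroc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_variance_matches_independent_reference(self):
        # frozen oracle: pROC 1.19 ci.auc(..., method="delong") on this dataset
        scores = np.array([0.9, 0.8, 0.35, 0.67, 0.45, 0.22, 0.58, 0.71,
                           0.15, 0.62, 0.44, 0.90, 0.05, 0.38, 0.81, 0.29])
        labels = np.array([1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 1, 0])
        auc, var = delong_auroc(scores, labels)
        assert auc == pytest.approx(0.828125, abs=1e-12)
        assert var == pytest.approx(1.276506696429e-02, rel=1e-9)
        m = confidence_intervals(scores, labels)
        assert m.ci["auroc"][0] == pytest.approx(0.606683181260, abs=1e-9)
        assert m.ci["auroc"][1] == 1.0  # truncated at 1

    def test_degenerate_interval_with_warning(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            m = confidence_intervals(scores, labels)
        assert m.ci["auroc"] == (1.0, 1.0)

    def test_ci_bounds_bracket_point(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        m = confidence_intervals(scores, labels)
        for metric, (lo, hi) in m.ci.items():
            point = getattr(m, metric)
            assert lo - 1e-12 <= point <= hi + 1e-12


class TestEnsemble:
    def test_identical_models_identity(self):
        assert ensemble_predict([0.42] * 20) == pytest.approx(0.42)

    def test_arithmetic_mean(self):
        assert ensemble_predict([0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_within_member_range(self, rng):
        vals = list(rng.random(20))
        assert min(vals) <= ensemble_predict(vals) <= max(vals)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([])


class TestMeanRocCurve:
    def test_monotone_between_0_and_1(self, rng):
        from auscult.evaluation import mean_roc_curve

        splits = []
        for _ in range(4):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            labels[:2] = [0, 1]
            splits.append((scores, labels))
        fpr, tpr = mean_roc_curve(splits)
        assert tpr[0] == 0.0 and tpr[-1] == 1.0
        assert np.all(np.diff(tpr) >= -1e-12)
        assert ((tpr >= 0) & (tpr <= 1)).all()


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        labels = list(DIAGNOSES) * 3
        mat = confusion_matrix(labels, labels)
        np.testing.assert_allclose(mat, np.eye(4))

    def test_rows_sum_to_one(self, rng):
        preds = [DIAGNOSES[i] for i in rng.integers(0, 4, 60)]
        truth = [DIAGNOSES[i] for i in rng.integers(0, 4, 60)]
        mat = confusion_matrix(preds, truth)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_average_of_normalized_matrices_is_row_stochastic(self, rng):
        mats = []
        for _ in range(5):
            preds = [DIAGNOSES[i] for i in rng.integers(0, 4, 40)]
            truth = [DIAGNOSES[i] for i in rng.integers(0, 4, 40)]
            mats.append(confusion_matrix(preds, truth))
        avg = np.mean(mats, axis=0)
        np.testing.assert_allclose(avg.sum(axis=1), 1.0, atol=1e-12)


class TestBaseline:
    def _cohort(self, rng, n=200):
        # bronchiolitis-like positives are infants with raised RR
        age_pos = rng.normal(0.8, 0.4, n // 2).clip(0.05, 16)
        age_neg = rng.normal(6.0, 3.0, n // 2).clip(0.05, 16)
        rr_pos = rng.normal(45, 10, n // 2)
        rr_neg = rng.normal(25, 6, n // 2)
        x = np.column_stack(
            [np.concatenate([age_pos, age_neg]), np.concatenate([rr_pos, rr_neg])]
        )
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        perm = rng.permutation(n)
        return x[perm], y[perm]

    def test_planted_age_effect_recovered(self, rng):
        x, y = self._cohort(rng)
        pipeline = fit_baseline(x[:120], y[:120], x[120:160], y[120:160])
        from sklearn.metrics import roc_auc_score

        held = baseline_predict(pipeline, x[160:])
        assert roc_auc_score(y[160:], held) > 0.8

    def test_affine_shift_invariance(self, rng):
        x, y = self._cohort(rng)
        pipeline = fit_baseline(x[:120], y[:120], x[120:160], y[120:160])
        scaler, model = pipeline
        shifted = scaler.transform(x[160:] + [10.0, 0.0])
        unshifted = scaler.transform(x[160:])
        # standardization makes predictions depend on z-scores only: refitting
        # on shifted data yields identical z-scores, hence identical outputs
        x2 = x + [10.0, 0.0]
        pipeline2 = fit_baseline(x2[:120], y[:120], x2[120:160], y[120:160])
        np.testing.assert_allclose(
            baseline_predict(pipeline2, x2[160:]),
            baseline_predict(pipeline, x[160:]),
            atol=1e-9,
        )

    def test_wrong_feature_count_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_baseline(np.ones((10, 3)), np.ones(10), np.ones((4, 3)), np.ones(4))

    def test_one_baseline_model_per_cv_split(self, rng):
        from auscult.evaluation import fit_baseline_cv

        patients = []
        for i in range(60):
            d = DIAGNOSES[i % 4]
            age = 0.8 if d == "bronchiolitis" else 6.0
            patients.append(
                PatientRecord(
                    f"p{i}", d, "c", age=age + rng.normal(0, 0.3),
                    respiratory_rate=30.0 + rng.normal(0, 5),
                )
            )
        patients[0].respiratory_rate = None  # excluded from the subset
        plan = make_nested_folds([p for p in patients if p.respiratory_rate], k=5, rng=0)
        pipelines = fit_baseline_cv(patients, plan, "bronchiolitis")
        assert len(pipelines) == 20
        scores = baseline_predict(pipelines[0], np.array([[0.8, 30.0], [6.0, 30.0]]))
        assert scores[0] > scores[1]  # infants score higher for bronchiolitis
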