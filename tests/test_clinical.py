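"""OCT-VF pairing, pluggable predictors, patient-level CV, paired bootstrap."""

from datetime import date

import numpy as np
import pytest

from rnflt.clinical import (
    auc_score,
    bootstrap_compare,
    crossval_compare,
    fold_t_test,
    pair_oct_vf,
    patient_folds,
    predict_progression,
    predict_vf,
)
from rnflt.errors import SplitError
from rnflt.maps import RNFLTMap
from tests.test_vf import make_exam


def _map_on(day):
    return RNFLTMap(values=np.full((8, 8), 90.0),
                    acquisition_date=date(2015, 1, 1).replace(day=1)
                    if day is None else make_exam(day).exam_date)


class TestPairing:
    def test_exam_thirty_days_out_is_paired(self):
        pairs = pair_oct_vf([_map_on(0)], [make_exam(30)])
        assert len(pairs) == 1

    def test_exam_thirty_one_days_out_is_dropped(self):
        pairs = pair_oct_vf([_map_on(0)], [make_exam(31)])
        assert pairs == []

    def test_nearest_exam_wins(self):
        near, far = make_exam(5, md=-1.0), make_exam(20, md=-9.0)
        pairs = pair_oct_vf([_map_on(0)], [far, near])
        assert pairs[0][1].md == -1.0

    def test_unreliable_exams_ignored(self):
        bad = make_exam(1, fl=0.9)
        ok = make_exam(25, md=-2.0)
        pairs = pair_oct_vf([_map_on(0)], [bad, ok])
        assert pairs[0][1].md == -2.0


class TestPredictors:
    def test_noiseless_affine_target_gives_unit_r2(self, rng):
        X = rng.uniform(50, 150, size=(40, 6))
        w = rng.normal(size=6)
        y = X @ w - 3.0
        est = predict_vf(X[:30], y[:30])
        from rnflt.clinical import evaluate_vf_predictor

        m = evaluate_vf_predictor(est, X[30:], y[30:])
        assert m["r2"] > 0.999999
        assert m["mae"] < 1e-8

    def test_multioutput_emits_per_location_metrics(self, rng):
        X = rng.uniform(size=(30, 4))
        Y = X @ rng.normal(size=(4, 52)) + rng.normal(0, 0.01, size=(30, 52))
        est = predict_vf(X, Y)
        from rnflt.clinical import evaluate_vf_predictor

        m = evaluate_vf_predictor(est, X, Y)
        assert m["per_location_r2"].shape == (52,)
        assert m["per_location_mae"].shape == (52,)

    def test_single_class_labels_rejected(self, rng):
        X = rng.uniform(size=(20, 3))
        with pytest.raises(ValueError):
            predict_progression(X, np.zeros(20))


class TestAUC:
    def test_equals_brute_force_concordance(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(size=n)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            assert auc_score(labels, scores) == pytest.approx(
                conc / (len(pos) * len(neg)), abs=1e-12
            )

    def test_null_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=2000)
        scores = rng.normal(size=2000)
        assert abs(auc_score(labels, scores) - 0.5) < 0.05

    def test_separable_scores_give_one(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auc_score(labels, scores) == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        scores = rng.normal(size=60)
        assert auc_score(labels, scores) == pytest.approx(
            auc_score(labels, np.exp(scores)), abs=1e-12
        )


class TestCrossValidation:
    def test_nine_patients_make_folds_of_three(self):
        folds = patient_folds([f"P{i}" for i in range(9)], k=3, seed=0)
        assert sorted(len(f) for f in folds) == [3, 3, 3]

    def test_folds_disjoint_and_cover(self):
        ids = [f"P{i}" for i in range(10)]
        folds = patient_folds(ids, k=3, seed=2)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(ids)

    def test_same_seed_same_folds(self):
        ids = [f"P{i}" for i in range(12)]
        assert patient_folds(ids, 3, 7) == patient_folds(ids, 3, 7)

    def test_more_folds_than_patients_raises(self):
        with pytest.raises(SplitError):
            patient_folds(["A", "B"], k=3)

    def test_compare_returns_paired_metrics(self, rng):
        n = 60
        pids = [f"P{i // 2}" for i in range(n)]
        X = rng.uniform(size=(n, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.1, size=n)
        Xn = X + rng.normal(0, 0.5, size=X.shape)     # degraded features
        df = crossval_compare(Xn, X, y, pids, k=3, seed=1)
        assert len(df) == 3
        assert {"mae_raw", "mae_corrected", "r2_raw", "r2_corrected"} <= set(df)
        diff, p = fold_t_test(df, "r2")
        assert diff > 0          # clean features predict better

    def test_classification_task_reports_auc(self, rng):
        n = 90
        pids = [f"P{i // 3}" for i in range(n)]
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
        df = crossval_compare(X, X, y, pids, model_kind="logistic",
                              task="classification", k=3, seed=0)
        assert {"auc_raw", "auc_corrected"} <= set(df)
        assert (df["auc_raw"] > 0.7).all()


class TestBootstrap:
    def test_identical_inputs_accept_null(self, rng):
        a = rng.normal(2.0, 1.0, size=50)
        res = bootstrap_compare(a, a.copy(), n_boot=500, seed=0)
        assert res.p_value == 1.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert res.difference == 0.0

    def test_clear_difference_is_detected(self, rng):
        a = rng.normal(5.0, 0.5, size=60)
        b = rng.normal(3.0, 0.5, size=60)
        res = bootstrap_compare(a, b, n_boot=500, seed=0)
        assert res.p_value < 0.01
        assert res.ci_high < 0.0

    def test_deterministic_given_seed(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        r1 = bootstrap_compare(a, b, n_boot=300, seed=9)
        r2 = bootstrap_compare(a, b, n_boot=300, seed=9)
        assert r1 == r2

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare(np.array([1.0]), np.array([2.0]))
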