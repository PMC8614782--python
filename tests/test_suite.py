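"""Split protocol, model adapters, metrics, LOOCV and the experiment grid."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from soacml.errors import CapabilityError
from soacml.suite import (ALGORITHMS, IMPORTANCE_CAPABLE, SplitSpec,
                          default_n_test, evaluate, fit_model, loocv,
                          make_estimator, run_experiment, split_dataset)
from soacml.synthetic import SyntheticSpec, generate_dataset
from soacml.table import DESCRIPTOR, FINGERPRINT_BIT

from conftest import FAST_HP, make_table

try:
    import catboost  # noqa: F401
    HAVE_CATBOOST = True
except ImportError:
    HAVE_CATBOOST = False


def _linear_data(n=40, p=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + noise * rng.normal(size=n)
    return make_table(X), pd.Series(y, index=[f"s{i:03d}" for i in range(n)])


class TestSplit:
    def test_canonical_split_is_66_8(self):
        t, y = _linear_data(n=74)
        spec = SplitSpec(n_total=74, n_test=default_n_test(74), random_state=0)
        (Xtr, ytr), (Xte, yte) = split_dataset(t, y, spec)
        assert Xtr.n_samples == 66 and Xte.n_samples == 8
        assert set(Xtr.sample_ids) | set(Xte.sample_ids) == set(t.sample_ids)
        assert not set(Xtr.sample_ids) & set(Xte.sample_ids)

    def test_split_deterministic(self):
        t, y = _linear_data(n=30)
        spec = SplitSpec(30, 5, random_state=10)
        (_, _), (Xte1, _) = split_dataset(t, y, spec)
        (_, _), (Xte2, _) = split_dataset(t, y, spec)
        assert Xte1.sample_ids == Xte2.sample_ids

    def test_three_states_give_distinct_partitions(self):
        t, y = _linear_data(n=74)
        parts = []
        for rs in (0, 10, 100):
            _, (Xte, _) = split_dataset(t, y, SplitSpec(74, 8, rs))
            parts.append(frozenset(Xte.sample_ids))
        assert len(set(parts)) == 3

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SplitSpec(10, 10)
        with pytest.raises(ValueError):
            SplitSpec(10, 0)

    def test_default_n_test_scales(self):
        assert default_n_test(74) == 8
        assert default_n_test(37) == 4
        assert default_n_test(5) == 1


class TestEvaluate:
    def _identity_model(self, t, y):
        return fit_model("lasso", {"alpha": 1e-10}, t.values, y)

    def test_perfect_predictions(self):
        t, y = _linear_data()
        m = self._identity_model(t, y)
        r2, rmse = evaluate(m, t.values, pd.Series(m.predict(t.values),
                                                   index=y.index))
        assert r2 == pytest.approx(1.0) and rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_case(self):
        # targets (0,0,1,1) vs predictions (0,1,1,1): SS_res=1, SS_tot=1
        class Const:
            feature_names = ["f00"]

            def predict(self, X):
                return np.array([0.0, 1.0, 1.0, 1.0])

        from soacml.suite import FittedModel
        m = FittedModel("lasso", None, ["f00"])
        m.predict = Const().predict
        X = pd.DataFrame({"f00": [0.0, 1, 2, 3]})
        r2, rmse = evaluate(m, X, pd.Series([0.0, 0.0, 1.0, 1.0]))
        assert rmse == pytest.approx(0.5)
        assert r2 == pytest.approx(0.0)

    def test_mean_prediction_scores_zero(self):
        t, y = _linear_data(n=20, noise=1.0, seed=3)

        from soacml.suite import FittedModel
        m = FittedModel("lasso", None, t.feature_names)
        mean = float(y.mean())
        m.predict = lambda X: np.full(len(X), mean)
        r2, _ = evaluate(m, t.values, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_targets_warn_nan_r2(self):
        t, y = _linear_data(n=10)
        m = fit_model("lasso", {"alpha": 1.0}, t.values, y)
        with pytest.warns(UserWarning, match="constant"):
            r2, rmse = evaluate(m, t.values, pd.Series(np.ones(10), index=y.index))
        assert math.isnan(r2) and rmse >= 0


class TestFitModel:
    def test_unknown_algorithm_lists_supported(self):
        with pytest.raises(ValueError, match="xgboost"):
            make_estimator("svm")

    def test_lasso_recovers_noiseless_linear_signal(self):
        t, y = _linear_data(n=60, noise=0.0)
        m = fit_model("lasso", {"alpha": 1e-4}, t.values.iloc[:40], y.iloc[:40])
        r2, _ = evaluate(m, t.values.iloc[40:], y.iloc[40:])
        assert r2 > 0.99

    def test_random_forest_constant_targets(self):
        t, _ = _linear_data(n=20)
        y = pd.Series(np.full(20, 3.25), index=t.sample_ids)
        m = fit_model("random_forest", {"n_estimators": 10}, t.values, y)
        assert np.allclose(m.predict(t.values), 3.25)

    @pytest.mark.parametrize("algorithm", ["xgboost", "lightgbm",
                                           "random_forest", "adaboost"])
    def test_tree_importance_length_matches_features(self, algorithm):
        t, y = _linear_data(n=30, p=5, noise=0.5)
        m = fit_model(algorithm, FAST_HP.get(algorithm), t.values, y)
        imp = m.importance()
        assert list(imp.index) == t.feature_names
        assert (imp >= 0).all()

    def test_lasso_importance_is_abs_coefficient(self):
        t, y = _linear_data(n=50, p=2, noise=0.0)
        m = fit_model("lasso", {"alpha": 1e-3}, t.values, y)
        coefs = m.estimator.named_steps["lasso"].coef_
        assert np.array_equal(m.importance().to_numpy(), np.abs(coefs))

    def test_dnn_has_no_importance(self):
        t, y = _linear_data(n=20)
        m = fit_model("dnn", FAST_HP["dnn"], t.values, y)
        with pytest.raises(CapabilityError):
            m.importance()

    @pytest.mark.skipif(HAVE_CATBOOST, reason="catboost installed here")
    def test_missing_library_raises_capability_error(self):
        with pytest.raises(CapabilityError, match="catboost"):
            make_estimator("catboost")

    def test_empty_training_set(self):
        t, y = _linear_data(n=5)
        with pytest.raises(ValueError):
            fit_model("lasso", None, t.values.iloc[:0], y.iloc[:0])


class _OneNN:
    """Hand-checkable 1-nearest-neighbour predictor for the LOOCV oracle."""

    def __init__(self, X, y):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.X[None, :, :]) ** 2).sum(-1)
        return self.y[d.argmin(axis=1)]


class TestLoocv:
    def test_fold_accounting(self):
        t, y = _linear_data(n=5)
        sizes = []

        def counting_fit(X, ytr):
            sizes.append(len(X))
            return _OneNN(X, ytr)

        loocv(counting_fit, None, t.values, y)
        assert sizes == [4] * 5  # exactly n fits, each on n-1 samples

    def test_zero_error_predictor(self):
        t, _ = _linear_data(n=6)
        y = pd.Series(np.zeros(6), index=t.sample_ids)
        assert loocv(lambda X, yy: _OneNN(X, yy), None, t.values, y) == 0.0

    def test_one_nn_matches_hand_enumeration(self):
        # 1-D points 0,1,2,10 with targets 0,1,4,9: LOO neighbour errors
        # |0-1|, |1-0|, |4-1|, |9-4| -> mean = 10/4
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0]})
        y = pd.Series([0.0, 1.0, 4.0, 9.0])
        score = loocv(lambda A, b: _OneNN(A, b), None, X, y)
        assert score == pytest.approx((1 + 1 + 3 + 5) / 4)

    def test_lasso_loocv_vanishes_without_regularization(self):
        t, y = _linear_data(n=20, noise=0.0, seed=5)
        strong = loocv("lasso", {"alpha": 1.0}, t.values, y)
        weak = loocv("lasso", {"alpha": 1e-6}, t.values, y)
        assert weak < strong
        assert weak == pytest.approx(0.0, abs=1e-3)

    def test_needs_three_samples(self):
        t, y = _linear_data(n=5)
        with pytest.raises(ValueError):
            loocv("lasso", None, t.values.iloc[:2], y.iloc[:2])


def _small_study(seed=0):
    spec = SyntheticSpec(n_samples=24, n_descriptors=5, n_fp_bits=16,
                         planted=(("desc_0001", 2.0), ("fp_0001", 1.0)),
                         noise_sd=0.3, fp_density=0.4, seed=seed)
    table, y, _ = generate_dataset(spec)
    desc = table.select([n for n in table.feature_names
                         if table.kind_of(n) == DESCRIPTOR])
    fp = table.select([n for n in table.feature_names
                       if table.kind_of(n) == FINGERPRINT_BIT])
    return desc, fp, y


class TestRunExperiment:
    def test_grid_shape_and_failures(self):
        desc, fp, y = _small_study()
        res = run_experiment(desc, fp, y, algorithms=ALGORITHMS,
                             random_states=(0, 10), hyperparameters=FAST_HP,
                             compute_loocv=False)
        n_available = len(ALGORITHMS) - (0 if HAVE_CATBOOST else 1)
        assert len(res.runs) == n_available * 2 * 2
        if not HAVE_CATBOOST:
            assert all("catboost" in msg for _, msg in res.failures)
            assert len(res.failures) == 4

    def test_dnn_disabled_shrinks_grid(self):
        desc, fp, y = _small_study()
        algos = [a for a in IMPORTANCE_CAPABLE if a != "catboost"]
        res = run_experiment(desc, fp, y, algorithms=algos,
                             random_states=(0,), hyperparameters=FAST_HP,
                             compute_loocv=False)
        assert len(res.runs) == len(algos) * 2
        assert res.failures == []

    def test_metric_invariants_across_grid(self):
        desc, fp, y = _small_study(seed=2)
        res = run_experiment(desc, fp, y,
                             algorithms=("lasso", "random_forest"),
                             random_states=(0, 10, 100),
                             hyperparameters=FAST_HP, compute_loocv=True)
        for run in res.runs:
            assert run.rmse >= 0
            assert run.r2 <= 1.0
            assert run.rmse_loo >= 0
            assert len(run.predictions) == default_n_test(24)

    def test_misaligned_inputs_rejected(self):
        desc, fp, y = _small_study()
        with pytest.raises(ValueError, match="aligned"):
            run_experiment(desc, fp, y.iloc[::-1],
                           algorithms=("lasso",), random_states=(0,))

    def test_grid_frame_columns(self):
        desc, fp, y = _small_study()
        res = run_experiment(desc, fp, y, algorithms=("lasso",),
                             random_states=(0,), compute_loocv=False)
        frame = res.to_frame()
        assert list(frame.columns) == ["algorithm", "feature_set",
                                       "random_state", "r2", "rmse", "rmse_loo"]
        assert len(frame) == 2
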