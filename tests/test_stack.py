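import warnings

import numpy as np
import pytest

from nrquant.stack import (LearnerSpec, cv_stack, default_library,
                           predict_ensemble, screen_correlation)


class TestDefaultLibrary:
    def test_continuous_has_eight_entries(self):
        lib = default_library("continuous")
        assert len(lib) == 8
        assert sum(s.screen == "corr" for s in lib) == 3

    def test_binary_has_ten_entries(self):
        lib = default_library("binary")
        assert len(lib) == 10
        assert sum(s.family == "bart" for s in lib) == 2

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            default_library("ordinal")

    def test_shrunk_library_still_stacks(self, rng):
        lib = [s for s in default_library("continuous")
               if s.family in ("mean", "linear")]
        X = rng.normal(size=(120, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 120)
        model = cv_stack(X, y, lib, "continuous", folds=4, seed=0)
        assert len(model.weights) == len(lib)


class TestScreening:
    def test_signal_column_retained(self, rng):
        X = rng.normal(size=(500, 10))
        y = 2.0 * X[:, 0]
        keep = screen_correlation(X, y, alpha=0.1)
        assert 0 in keep

    def test_alpha_one_keeps_all_nonconstant(self, rng):
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        assert len(screen_correlation(X, y, alpha=1.0)) == 5

    def test_null_retention_near_alpha_d(self):
        # under the null, #retained ~ Binomial(d, alpha)
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(40):
            X = rng.normal(size=(1000, 20))
            y = rng.normal(size=1000)
            counts.append(len(screen_correlation(X, y, alpha=0.1)))
        assert abs(np.mean(counts) - 2.0) < 0.8

    def test_never_empty(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        keep = screen_correlation(X, y, alpha=1e-12)
        assert len(keep) == 1

    def test_constant_column_warned_and_excluded(self, rng):
        X = rng.normal(size=(100, 3))
        X[:, 1] = 5.0
        y = X[:, 0]
        with pytest.warns(UserWarning, match="constant"):
            keep = screen_correlation(X, y, alpha=1.0)
        assert 1 not in keep


class TestCvStack:
    def test_mean_only_library(self, rng):
        X = rng.normal(size=(100, 2))
        y = rng.normal(3.0, 1.0, 100)
        model = cv_stack(X, y, [LearnerSpec("mean", "mean")], "continuous",
                         seed=0)
        assert model.weights.tolist() == [1.0]
        np.testing.assert_allclose(predict_ensemble(model, X), y.mean())

    def test_true_model_dominates(self, rng):
        X = rng.normal(size=(2000, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.05, 2000)
        lib = [LearnerSpec("mean", "mean"), LearnerSpec("ols", "linear")]
        model = cv_stack(X, y, lib, "continuous", folds=5, seed=0)
        assert model.weights[1] > 0.9

    def test_duplicate_learners_same_prediction(self, rng):
        X = rng.normal(size=(300, 3))
        y = X[:, 0] + rng.normal(0, 0.3, 300)
        lib1 = [LearnerSpec("ols", "linear"), LearnerSpec("mean", "mean")]
        lib2 = [LearnerSpec("ols", "linear"), LearnerSpec("ols2", "linear"),
                LearnerSpec("mean", "mean")]
        m1 = cv_stack(X, y, lib1, "continuous", folds=5, seed=0)
        m2 = cv_stack(X, y, lib2, "continuous", folds=5, seed=0)
        np.testing.assert_allclose(predict_ensemble(m1, X),
                                   predict_ensemble(m2, X), atol=1e-3)

    def test_oof_risk_optimality(self, rng):
        X = rng.normal(size=(400, 5))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.2, 400)
        lib = [s for s in default_library("continuous")
               if s.family != "random_forest"]
        model = cv_stack(X, y, lib, "continuous", folds=5, seed=1)
        assert model.ensemble_cv_risk <= model.cv_risks.min() + 1e-8

    def test_weights_on_simplex(self, rng):
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(float)
        lib = [LearnerSpec("mean", "mean"), LearnerSpec("logit", "linear"),
               LearnerSpec("lasso", "lasso")]
        model = cv_stack(X, y, lib, "binary", folds=4, seed=0)
        assert (model.weights >= 0).all()
        assert model.weights.sum() == pytest.approx(1.0)

    def test_missing_X_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            cv_stack(X, np.zeros(50), [LearnerSpec("mean", "mean")],
                     "continuous")

    def test_duplicate_ids_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        lib = [LearnerSpec("m", "mean"), LearnerSpec("m", "linear")]
        with pytest.raises(ValueError, match="unique"):
            cv_stack(X, np.zeros(50), lib, "continuous")

    def test_deterministic(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(0, 0.5, 200)
        lib = [LearnerSpec("mean", "mean"), LearnerSpec("ols", "linear"),
               LearnerSpec("rf", "random_forest")]
        m1 = cv_stack(X, y, lib, "continuous", folds=4, seed=5)
        m2 = cv_stack(X, y, lib, "continuous", folds=4, seed=5)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_rare_class_fallback(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.zeros(40)
        y[3] = 1.0
        lib = [LearnerSpec("mean", "mean"), LearnerSpec("logit", "linear")]
        model = cv_stack(X, y, lib, "binary", folds=5, seed=0)
        assert model.weights.sum() == pytest.approx(1.0)


class TestStratifiedLearner:
    def test_matches_brute_force_group_means(self, rng):
        n = 500
        rx = rng.choice([0.0, 50.0, 150.0, 400.0], n)
        dd = rng.choice([0.0, 5.0, 30.0], n)
        noise = rng.normal(size=n)
        y = rx * 0.3 + dd + noise
        X = np.column_stack([rx, dd, noise])
        cols = ["prescribed_mme", "discharge_day_mme", "junk"]
        model = cv_stack(X, y, [LearnerSpec("strat", "stratified")],
                         "continuous", seed=0, columns=cols)
        pred = predict_ensemble(model, X, columns=cols)
        import pandas as pd
        df = pd.DataFrame({"rx": rx, "dd": dd, "y": y})
        means = df.groupby(["rx", "dd"])["y"].transform("mean").to_numpy()
        np.testing.assert_allclose(pred, means, atol=1e-9)

    def test_empty_stratum_falls_back_to_grand_mean(self, rng):
        X = np.column_stack([np.full(50, 50.0), np.zeros(50)])
        y = rng.normal(size=50)
        model = cv_stack(X, y, [LearnerSpec("strat", "stratified")],
                         "continuous", seed=0,
                         columns=["prescribed_mme", "discharge_day_mme"])
        X_new = np.array([[500.0, 40.0]])  # unseen stratum
        pred = predict_ensemble(model, X_new,
                                columns=["prescribed_mme", "discharge_day_mme"])
        assert pred[0] == pytest.approx(y.mean())


class TestPredictEnsemble:
    def _model(self, rng, lib):
        X = rng.normal(size=(150, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 150)
        return cv_stack(X, y, lib, "continuous", folds=4, seed=0,
                        columns=["a", "b", "c"]), X

    def test_degenerate_weight_equals_single_learner(self, rng):
        model, X = self._model(rng, [LearnerSpec("ols", "linear"),
                                     LearnerSpec("mean", "mean")])
        model.weights = np.array([1.0, 0.0])
        np.testing.assert_allclose(predict_ensemble(model, X),
                                   model.learners[0].predict(X))

    def test_constant_learners_give_constant(self, rng):
        model, X = self._model(rng, [LearnerSpec("mean", "mean"),
                                     LearnerSpec("mean2", "mean")])
        pred = predict_ensemble(model, X)
        assert np.allclose(pred, pred[0])

    def test_convexity_bounds(self, rng):
        model, X = self._model(rng, [LearnerSpec("ols", "linear"),
                                     LearnerSpec("mean", "mean"),
                                     LearnerSpec("lasso", "lasso")])
        base = np.column_stack([l.predict(X) for l in model.learners])
        active = model.weights > 0
        ens = predict_ensemble(model, X)
        assert (ens <= base[:, active].max(axis=1) + 1e-9).all()
        assert (ens >= base[:, active].min(axis=1) - 1e-9).all()

    def test_column_mismatch_named(self, rng):
        model, X = self._model(rng, [LearnerSpec("mean", "mean"),
                                     LearnerSpec("ols", "linear")])
        with pytest.raises(ValueError, match="column mismatch"):
            predict_ensemble(model, X, columns=["a", "b", "zzz"])

    def test_binary_output_clipped(self, rng):
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(float)
        model = cv_stack(X, y, [LearnerSpec("logit", "linear")], "binary",
                         seed=0)
        p = predict_ensemble(model, 10 * X)
        assert p.min() >= 1e-6 and p.max() <= 1 - 1e-6


def test_bart_learner_in_stack(rng):
    # small sum-of-trees members keep the 10-entry binary library runnable
    X = rng.normal(size=(150, 3))
    y = (X[:, 0] + 0.3 * rng.normal(size=150) > 0).astype(float)
    lib = [LearnerSpec("mean", "mean"),
           LearnerSpec("bart", "bart", hyperparameters=(
               ("n_trees", 10), ("n_burn", 20), ("n_draw", 20)))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cv_stack(X, y, lib, "binary", folds=3, seed=0)
    assert model.ensemble_cv_risk <= model.cv_risks.min() + 1e-8
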