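import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from nrquant import synthcohort as sc
from nrquant.drquantile import (TargetedCDF, adjusted_quantiles,
                                fit_propensity, fit_threshold_regressions,
                                invert_quantile, make_grid, target_cdf,
                                unadjusted_quantile, estimate_by_procedure)
from nrquant.stack import LearnerSpec

MEAN_LIB = [LearnerSpec("mean", "mean")]
LOGIT_LIB = [LearnerSpec("logit", "linear")]


class TestPropensity:
    def test_all_measured_gives_unit_weights(self, rng):
        X = rng.normal(size=(100, 2))
        fit = fit_propensity(X, np.ones(100), MEAN_LIB)
        np.testing.assert_allclose(fit.probabilities, 1.0)
        np.testing.assert_allclose(fit.weights, 1.0)

    def test_recovers_known_logistic(self, rng):
        n = 5000
        X = rng.normal(size=(n, 2))
        p = expit(-0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1])
        d = (rng.random(n) < p).astype(float)
        fit = fit_propensity(X, d, LOGIT_LIB, seed=0)
        assert np.corrcoef(fit.raw_probabilities, p)[0, 1] > 0.8

    def test_bounds_cap_weights(self, rng):
        n = 2000
        X = rng.normal(size=(n, 1))
        p = expit(-4 + 3 * X[:, 0])
        d = (rng.random(n) < p).astype(float)
        fit = fit_propensity(X, d, LOGIT_LIB, bounds=(0.01, 1.0), seed=0)
        assert fit.weights.max() <= 100.0 + 1e-9

    def test_invalid_bounds_rejected(self, rng):
        X = rng.normal(size=(20, 1))
        with pytest.raises(ValueError, match="bounds"):
            fit_propensity(X, np.ones(20), MEAN_LIB, bounds=(0.0, 1.0))


class TestThresholdRegressions:
    def test_top_threshold_is_one(self, rng):
        n = 300
        X = rng.normal(size=(n, 2))
        y = np.abs(rng.normal(size=n))
        grid = make_grid(y)
        fits = fit_threshold_regressions(X, y, np.ones(n), grid, MEAN_LIB)
        assert fits.initial_cdf[-1] == pytest.approx(1.0)

    def test_mcar_initial_cdf_matches_responder_ecdf(self, rng):
        n = 4000
        X = rng.normal(size=(n, 2))
        y = np.abs(rng.normal(size=n)) * 10
        d = (rng.random(n) < 0.4)
        grid = np.quantile(y[d], [0.25, 0.5, 0.75])
        fits = fit_threshold_regressions(X, np.where(d, y, np.nan), d.astype(float),
                                         grid, MEAN_LIB)
        ecdf = [(y[d] <= t).mean() for t in grid]
        np.testing.assert_allclose(fits.initial_cdf, ecdf, atol=1e-12)

    def test_negative_grid_rejected(self, rng):
        X = rng.normal(size=(50, 1))
        with pytest.raises(ValueError):
            fit_threshold_regressions(X, np.ones(50), np.ones(50),
                                      np.array([-1.0, 2.0]), MEAN_LIB)

    def test_no_measured_rejected(self, rng):
        X = rng.normal(size=(50, 1))
        with pytest.raises(ValueError, match="measured"):
            fit_threshold_regressions(X, np.ones(50), np.zeros(50),
                                      np.array([1.0]), MEAN_LIB)


class TestTargeting:
    def test_full_response_equals_ecdf(self, rng):
        n = 400
        X = rng.normal(size=(n, 3))
        y = np.round(rng.gamma(2.0, 20.0, n), 1)
        ests, tcdf = adjusted_quantiles(X, y, np.ones(n), [0.5, 0.75],
                                        propensity_library=MEAN_LIB,
                                        outcome_library=MEAN_LIB, seed=0)
        ecdf = np.array([(y <= t).mean() for t in tcdf.grid])
        assert np.abs(tcdf.targeted - ecdf).max() < 1e-6
        for level in (0.5, 0.75):
            emp = np.quantile(y, level, method="inverted_cdf")
            est = [e for e in ests if e.level == level][0]
            assert est.point == pytest.approx(emp)

    def test_influence_curve_mean_zero(self, rng):
        df = sc.simple_confounded_sim(3000, seed=4)
        X = df[["w"]].to_numpy()
        y = np.nan_to_num(df["y"].to_numpy())
        d = df["measured"].to_numpy(dtype=float)
        grid = make_grid(y[d == 1], 31)
        prop = fit_propensity(X, d, LOGIT_LIB, seed=0)
        fits = fit_threshold_regressions(X, y, d, grid, MEAN_LIB, seed=0)
        tcdf = target_cdf(fits, prop, d, y)
        # recompute the influence curve from the recorded fluctuations
        g = prop.probabilities
        h = 1.0 / g
        for j in range(len(grid)):
            if fits.models[j] is None:
                continue
            q = np.clip(fits.predictions[:, j], 1e-6, 1 - 1e-6)
            q_star = expit(logit(q) + tcdf.epsilon[j] * h)
            b = np.where(d == 1, (y <= grid[j]).astype(float), 0.0)
            ic = d * h * (b - q_star) + q_star - q_star.mean()
            assert abs(ic.mean()) < 1e-8

    def test_targeted_cdf_in_unit_interval_and_monotone(self, rng):
        df = sc.simple_confounded_sim(2000, seed=5)
        ests, tcdf = adjusted_quantiles(
            df[["w"]].to_numpy(), np.nan_to_num(df["y"].to_numpy()),
            df["measured"].to_numpy(float), [0.5],
            propensity_library=LOGIT_LIB, outcome_library=MEAN_LIB, seed=1)
        assert tcdf.targeted.min() >= 0.0 and tcdf.targeted.max() <= 1.0
        assert (np.diff(tcdf.targeted) >= -1e-12).all()

    def test_monotonization_preserves_monotone_input(self):
        grid = np.array([0.0, 1.0, 2.0])
        from sklearn.isotonic import IsotonicRegression
        vals = np.array([0.1, 0.5, 0.9])
        out = IsotonicRegression(y_min=0, y_max=1).fit_transform(grid, vals)
        np.testing.assert_allclose(out, vals)


class TestInversion:
    def _step(self):
        return TargetedCDF(grid=np.array([0.0, 30.0, 60.0]),
                           initial=np.array([0.0, 1.0, 1.0]),
                           epsilon=np.zeros(3),
                           targeted=np.array([0.0, 1.0, 1.0]),
                           ic_variance=np.zeros(3), n=100)

    def test_step_function_returns_jump_point(self):
        t = self._step()
        for level in (0.1, 0.5, 0.9):
            assert invert_quantile(t, level).point == 30.0

    def test_monotone_in_level(self, rng):
        df = sc.simple_confounded_sim(1500, seed=6)
        ests, _ = adjusted_quantiles(
            df[["w"]].to_numpy(), np.nan_to_num(df["y"].to_numpy()),
            df["measured"].to_numpy(float), [0.5, 0.75],
            propensity_library=LOGIT_LIB, outcome_library=MEAN_LIB, seed=0)
        assert ests[1].point >= ests[0].point

    def test_level_above_grid_rejected(self):
        t = self._step()
        t.targeted = np.array([0.0, 0.3, 0.4])
        with pytest.raises(ValueError, match="grid too short"):
            invert_quantile(t, 0.9)

    def test_ci_contains_point(self, rng):
        df = sc.simple_confounded_sim(1500, seed=8)
        ests, _ = adjusted_quantiles(
            df[["w"]].to_numpy(), np.nan_to_num(df["y"].to_numpy()),
            df["measured"].to_numpy(float), [0.5],
            propensity_library=LOGIT_LIB, outcome_library=MEAN_LIB, seed=0)
        e = ests[0]
        assert e.ci_low <= e.point <= e.ci_high


class TestUnadjusted:
    def test_type1_convention(self):
        assert unadjusted_quantile([0, 0, 0, 10], 0.5).point == 0.0

    def test_constant_sample(self):
        for level in (0.2, 0.5, 0.9):
            assert unadjusted_quantile([7.5] * 5, level).point == 7.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unadjusted_quantile([], 0.5)

    def test_mcar_adjusted_close_to_unadjusted(self, rng):
        # MCAR response: no correction expected beyond noise
        n = 8000
        y = rng.lognormal(3.0, 0.6, n)
        d = (rng.random(n) < 0.3).astype(float)
        X = rng.normal(size=(n, 1))
        ests, _ = adjusted_quantiles(X, np.where(d == 1, y, 0.0), d, [0.5],
                                     propensity_library=LOGIT_LIB,
                                     outcome_library=MEAN_LIB, seed=0)
        una = unadjusted_quantile(y[d == 1], 0.5)
        assert una.ci_low <= ests[0].point <= una.ci_high


class TestByProcedure:
    def _records(self, n=300, groups=("a", "b"), full_response=True, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.choice(groups, n)
        rx = np.full(n, 150.0)
        y = np.round(rng.uniform(0, 150, n) / 7.5) * 7.5
        responded = np.ones(n) if full_response else (rng.random(n) < 0.5)
        df = pd.DataFrame({
            "procedure_group": g, "prescribed_mme": rx,
            "measured": responded.astype(int),
            "consumed_mme": np.where(responded, y, np.nan),
            "w1": rng.normal(size=n),
        })
        return df

    def _config(self, **kw):
        cfg = {"predictor_columns": ["w1"], "levels": [0.5, 0.75],
               "min_group_n": 30, "folds": 4, "seed": 0,
               "outcome_library": MEAN_LIB, "propensity_library": MEAN_LIB,
               "grid_max_points": 101}
        cfg.update(kw)
        return cfg

    def test_full_response_adjusted_equals_unadjusted(self):
        df = self._records()
        table, _ = estimate_by_procedure(df, self._config())
        for (grp, lvl), sub in table.groupby(["procedure_group", "level"]):
            adj = sub[sub.method == "adjusted"]["point"].iloc[0]
            una = sub[sub.method == "unadjusted"]["point"].iloc[0]
            assert adj == pytest.approx(una)

    def test_small_group_skipped(self):
        df = self._records(n=200, groups=("big",))
        tiny = self._records(n=5, groups=("tiny",), seed=1)
        table, notices = estimate_by_procedure(
            pd.concat([df, tiny], ignore_index=True), self._config())
        assert set(table["procedure_group"]) == {"big"}
        assert any("tiny" in n for n in notices)

    def test_all_population_mixes_known_zeros(self):
        df = self._records(n=400, groups=("a",))
        zeros = pd.DataFrame({
            "procedure_group": ["a"] * 400, "prescribed_mme": 0.0,
            "measured": 1, "consumed_mme": 0.0, "w1": 0.0,
        })
        both = pd.concat([df, zeros], ignore_index=True)
        t_all, _ = estimate_by_procedure(both, self._config(population="all"))
        adj = t_all[(t_all.method == "adjusted") & (t_all.level == 0.5)]
        # half the cohort are known zeros, so the all-patients median is ~0
        assert adj["point"].iloc[0] <= 7.5


def test_consistency_rmse_shrinks_with_n():
    # scaled-down consistency check against the exact generator quantile
    truth = sc.simple_sim_true_quantile(0.5)
    errs = {}
    for n in (1000, 8000):
        pts = []
        for r in range(10):
            df = sc.simple_confounded_sim(n, seed=1000 * n + r)
            ests, _ = adjusted_quantiles(
                df[["w"]].to_numpy(), np.nan_to_num(df["y"].to_numpy()),
                df["measured"].to_numpy(float), [0.5],
                propensity_library=LOGIT_LIB, outcome_library=MEAN_LIB,
                seed=r, grid_max_points=81)
            pts.append(ests[0].point)
        errs[n] = np.sqrt(np.mean((np.array(pts) - truth) ** 2))
    assert errs[8000] < errs[1000]
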