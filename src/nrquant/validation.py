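"""Monte-Carlo validation studies for the targeted quantile estimator.

Shared by the test suite and the acceptance report: double-robustness bias
experiments, confidence-interval coverage, null calibration of the
bivariate diagnostics, and planted-signal importance replicates.

The estimator experiments use the compact one-binary-confounder generator
(:func:`nrquant.synthcohort.simple_confounded_sim`), where a logistic model
in W is saturated — exactly correct — so "the library contains the truth"
is literal: the correct nuisance library is a single logistic learner and
the misspecified one is the constant (mean) learner.
"""

from __future__ import annotations

import numpy as np

from . import synthcohort as sc
from .drquantile import adjusted_quantiles, unadjusted_quantile
from .stack import LearnerSpec

__all__ = ["dr_bias_experiment", "coverage_experiment",
           "null_pvalue_experiment", "importance_replicates"]

_LOGIT_LIB = [LearnerSpec("logit", "linear")]
_MEAN_LIB = [LearnerSpec("mean", "mean")]


def _one_replicate(n: int, seed: int, scenario: str, level: float,
                   grid_max_points: int):
    df = sc.simple_confounded_sim(n, seed=seed)
    X = df[["w"]].to_numpy()
    y = np.nan_to_num(df["y"].to_numpy())
    m = df["measured"].to_numpy(dtype=float)
    if scenario == "propensity_correct":
        prop_lib, out_lib = _LOGIT_LIB, _MEAN_LIB
    elif scenario == "outcome_correct":
        prop_lib, out_lib = _MEAN_LIB, _LOGIT_LIB
    elif scenario == "both_correct":
        prop_lib, out_lib = _LOGIT_LIB, _LOGIT_LIB
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    ests, _ = adjusted_quantiles(
        X, y, m, [level], propensity_library=prop_lib,
        outcome_library=out_lib, seed=seed, grid_max_points=grid_max_points)
    naive = unadjusted_quantile(df["y"].to_numpy()[m == 1], level)
    return ests[0], naive


def dr_bias_experiment(scenario: str, *, n: int = 20_000, reps: int = 50,
                       level: float = 0.5, seed: int = 0,
                       grid_max_points: int = 101) -> dict:
    """Bias of the targeted vs naive responder quantile under one correct
    and one misspecified nuisance model.

    Returns the exact generating-distribution quantile, mean estimates,
    biases, and the Monte-Carlo standard error of the targeted mean.
    """
    truth = sc.simple_sim_true_quantile(level)
    tmle, naive = [], []
    for r in range(reps):
        e, u = _one_replicate(n, seed * 100_003 + r, scenario, level,
                              grid_max_points)
        tmle.append(e.point)
        naive.append(u.point)
    tmle, naive = np.asarray(tmle), np.asarray(naive)
    return {
        "scenario": scenario,
        "truth": truth,
        "tmle_mean": float(tmle.mean()),
        "naive_mean": float(naive.mean()),
        "tmle_bias": float(tmle.mean() - truth),
        "naive_bias": float(naive.mean() - truth),
        "tmle_mc_se": float(tmle.std(ddof=1) / np.sqrt(reps)),
        "naive_mc_se": float(naive.std(ddof=1) / np.sqrt(reps)),
        "n": n,
        "reps": reps,
    }


def coverage_experiment(*, n: int = 5_000, reps: int = 200, level: float = 0.5,
                        seed: int = 0, grid_max_points: int = 81) -> dict:
    """Empirical 95% CI coverage of the true median, both nuisances correct."""
    truth = sc.simple_sim_true_quantile(level)
    hits = 0
    for r in range(reps):
        e, _ = _one_replicate(n, seed * 100_003 + r, "both_correct", level,
                              grid_max_points)
        if e.ci_low <= truth <= e.ci_high:
            hits += 1
    return {"truth": truth, "coverage": hits / reps, "n": n, "reps": reps}


def null_pvalue_experiment(*, reps: int = 200, n: int = 1200, seed: int = 0,
                           covariate: str = "tobacco_use") -> np.ndarray:
    """Chi-squared p-values across replicate cohorts where response is
    independent of every covariate (all response coefficients zero)."""
    from .bivariate import test_association

    pvals = np.empty(reps)
    zero_coefs = {k: 0.0 for k in sc.DEFAULT_RESPONSE_COEFS}
    for r in range(reps):
        params = sc.CohortParams(n_patients=n, seed=seed * 7919 + r,
                                 response_coefficients=dict(zero_coefs))
        df = sc.generate_cohort(params)
        pvals[r] = test_association(df, covariate, "responded").p_value
    return pvals


def importance_replicates(*, reps: int = 10, n: int = 2500, seed: int = 0,
                          top: int = 3) -> dict:
    """Fraction of replicates where the planted response drivers (age and
    tobacco) both rank in the top of the measurement importance table."""
    from .treeimp import importance_analysis

    planted = {
        "age_18_45": -1.4, "age_61_70": 1.4, "age_71_95": 0.7,
        "tobacco_past_month": -2.5, "tobacco_1_12_months": -1.5,
        "tobacco_history": 1.3,
    }
    hits = 0
    for r in range(reps):
        params = sc.CohortParams(n_patients=n, seed=seed * 104_729 + r,
                                 response_coefficients=dict(planted))
        df = sc.generate_cohort(params)
        table_a, _ = importance_analysis(df, k=10, seed=r)
        top_vars = table_a.top(top)
        if "age_years" in top_vars and "tobacco_use" in top_vars:
            hits += 1
    return {"fraction": hits / reps, "reps": reps, "top": top}
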