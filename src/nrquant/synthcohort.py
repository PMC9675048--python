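"""Synthetic surgical cohorts with informative nonresponse.

Generates per-patient tables with EHR-style covariates, a logistic survey
response model, and consumption bounded by prescription size, plus
large-sample ground-truth quantile oracles used to validate the estimators.

Randomness is driven by a single integer seed through a counter-based
(Philox) generator with a fixed sub-stream per stage, so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "CohortParams",
    "generate_cohort",
    "inject_missingness",
    "true_quantile",
    "simple_confounded_sim",
    "simple_sim_true_quantile",
    "default_missingness_spec",
    "COVARIATE_COLUMNS",
    "PROTECTED_COLUMNS",
]

# Stage ids feed the Philox key so sub-streams never collide.
_STAGES = {
    "covariates": 1,
    "prescription": 2,
    "response": 3,
    "outcome": 4,
    "missingness": 5,
    "oracle": 6,
}

AGE_BINS = [(18, 46), (46, 61), (61, 71), (71, 96)]
AGE_BIN_LABELS = ["18-45", "46-60", "61-70", "71-95"]
TOBACCO_LEVELS = ["never", "past month", "1-12 months", "history"]
ALCOHOL_LEVELS = ["never", "occasionally", "daily"]
RACE_LEVELS = ["White", "Asian", "Black", "Hispanic", "Other"]
LOS_LEVELS = ["outpatient", "1-2 days", "3-15 days"]
SEX_LEVELS = ["female", "male"]

#: covariate columns of a generated record (targets of missingness injection)
COVARIATE_COLUMNS = [
    "age_years", "sex", "race", "tobacco_use", "alcohol_use", "asa_class",
    "los_category", "preop_assessment", "opioid_drugs_prescribed",
    "prescribed_mme", "discharge_day_mme",
]

#: outcome / flag columns that inject_missingness refuses to mask
PROTECTED_COLUMNS = {"patient_id", "responded", "measured", "consumed_mme"}

# (label, mix weight, typical prescription MME) for the ten common procedures
DEFAULT_PROCEDURE_MIX: list[tuple[str, float, float]] = [
    ("spinal fusion/laminectomy", 0.14, 350.0),
    ("anterior cervical discectomy fusion", 0.07, 300.0),
    ("microdiscectomy", 0.08, 225.0),
    ("sternotomy", 0.10, 180.0),
    ("reduction mammoplasty", 0.09, 150.0),
    ("open inguinal hernia repair", 0.11, 100.0),
    ("cholecystectomy", 0.12, 90.0),
    ("laparoscopic appendectomy", 0.10, 75.0),
    ("carpal tunnel release", 0.10, 45.0),
    ("thyroidectomy", 0.09, 40.0),
]

# Log-odds response effects; reference levels carry 0.  Directions: higher
# response for ages 61-70, never/history smokers, daily alcohol; magnitudes
# chosen so covariate-stratified response rates span roughly 12-28%.
DEFAULT_RESPONSE_COEFS: dict[str, float] = {
    "age_18_45": -0.30,
    "age_61_70": 0.35,
    "age_71_95": -0.15,
    "tobacco_past_month": -0.55,
    "tobacco_1_12_months": -0.10,
    "tobacco_history": 0.08,
    "alcohol_never": -0.22,
    "alcohol_daily": 0.45,
    "race_asian": -0.15,
    "race_black": -0.65,
    "race_hispanic": -0.65,
    "race_other": -0.35,
    "los_1_2": 0.18,
    "los_3_15": -0.04,
    "rx_300plus": -0.10,
}

# Consumed fraction of the prescription: zero-inflated Beta whose mean
# depends on age, recent tobacco use and discharge-day MMEs.
DEFAULT_OUTCOME_MODEL: dict[str, float] = {
    "zero_prob": 0.15,
    "mu_intercept": -0.35,
    "mu_age_per_decade": -0.12,     # centered at age 60
    "mu_tobacco_recent": 0.45,      # past month or 1-12 months
    "mu_dd_per_10mme": 0.25,        # discharge-day MMEs, capped at 30
    "precision": 4.0,
}


def default_missingness_spec() -> dict:
    """Missingness spec matching the study table: a 13.5% preoperative
    assessment block (alcohol + ASA masked together, flag recorded) plus
    light MCAR holes in two numeric covariates."""
    return {
        "columns": {
            "discharge_day_mme": {"rate": 0.02},
            "age_years": {"rate": 0.01},
        },
        "blocks": [
            {
                "name": "preop",
                "rate": 0.135,
                "columns": ["alcohol_use", "asa_class"],
                "flag_column": "preop_assessment",
            }
        ],
    }


@dataclass
class CohortParams:
    """Parameters of the synthetic data-generating process."""

    n_patients: int = 5000
    zero_rx_fraction: float = 0.29
    response_rate_target: float = 0.205
    procedure_mix: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_PROCEDURE_MIX))
    age_bin_probs: tuple[float, ...] = (0.240, 0.319, 0.261, 0.180)
    sex_probs: tuple[float, ...] = (0.522, 0.478)
    race_probs: tuple[float, ...] = (0.729, 0.026, 0.111, 0.019, 0.115)
    tobacco_probs: tuple[float, ...] = (0.549, 0.092, 0.030, 0.329)
    alcohol_probs: tuple[float, ...] = (0.284, 0.632, 0.084)
    asa_probs: tuple[float, ...] = (0.080, 0.492, 0.350, 0.060, 0.018)
    los_probs: tuple[float, ...] = (0.417, 0.311, 0.272)
    multi_drug_prob: float = 0.031   # P(2-3 drugs | any prescription)
    rx_sigma: float = 0.5            # lognormal spread around procedure MME
    dd_zero_prob_unprescribed: float = 0.85
    dd_zero_prob_prescribed: float = 0.554
    n_months: int = 20
    start_month: str = "2019-03"
    mme_drift_per_month: float = 0.0  # relative drift in prescription size
    response_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_COEFS))
    response_intercept: float | None = None   # None => calibrate to target
    outcome_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MODEL))
    missingness_spec: dict = field(default_factory=default_missingness_spec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("zero_rx_fraction", "response_rate_target",
                     "multi_drug_prob", "dd_zero_prob_unprescribed",
                     "dd_zero_prob_prescribed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        w = np.array([p[1] for p in self.procedure_mix], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ValueError("procedure_mix weights must be >= 0 and sum to 1")
        if any(p[2] < 0 for p in self.procedure_mix):
            raise ValueError("procedure_mix typical_rx_mme must be >= 0")
        for name in ("age_bin_probs", "sex_probs", "race_probs",
                     "tobacco_probs", "alcohol_probs", "asa_probs",
                     "los_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        if "zero_prob" in self.outcome_model and not (
                0.0 <= self.outcome_model["zero_prob"] <= 1.0):
            raise ValueError("outcome_model['zero_prob'] must be in [0, 1]")

    def replace(self, **kw) -> "CohortParams":
        return dataclasses.replace(self, **kw)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, _STAGES[stage]]))


def _norm(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def _month_labels(start: str, n: int) -> list[str]:
    y, m = (int(t) for t in start.split("-"))
    out = []
    for _ in range(n):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def _response_linear_predictor(df: pd.DataFrame,
                               coefs: dict[str, float]) -> np.ndarray:
    """Map named log-odds effects onto drawn covariates."""
    lp = np.zeros(len(df))
    age = df["age_years"].to_numpy()
    features = {
        "age_18_45": age < 46,
        "age_46_60": (age >= 46) & (age < 61),
        "age_61_70": (age >= 61) & (age < 71),
        "age_71_95": age >= 71,
        "tobacco_past_month": df["tobacco_use"].to_numpy() == "past month",
        "tobacco_1_12_months": df["tobacco_use"].to_numpy() == "1-12 months",
        "tobacco_history": df["tobacco_use"].to_numpy() == "history",
        "alcohol_never": df["alcohol_use"].to_numpy() == "never",
        "alcohol_daily": df["alcohol_use"].to_numpy() == "daily",
        "race_asian": df["race"].to_numpy() == "Asian",
        "race_black": df["race"].to_numpy() == "Black",
        "race_hispanic": df["race"].to_numpy() == "Hispanic",
        "race_other": df["race"].to_numpy() == "Other",
        "los_1_2": df["los_category"].to_numpy() == "1-2 days",
        "los_3_15": df["los_category"].to_numpy() == "3-15 days",
        "sex_male": df["sex"].to_numpy() == "male",
        "rx_300plus": df["prescribed_mme"].to_numpy() >= 300,
    }
    for name, coef in coefs.items():
        if name not in features:
            raise ValueError(f"unknown response coefficient: {name!r}")
        lp += coef * features[name].astype(float)
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) = target."""
    if np.allclose(lp, 0.0):
        return float(logit(target))
    f = lambda c: float(np.mean(expit(c + lp))) - target
    return brentq(f, -20.0, 20.0)


def _consumed_fraction_mean(df: pd.DataFrame, om: dict[str, float]) -> np.ndarray:
    age = df["age_years"].to_numpy(dtype=float)
    tob = df["tobacco_use"].to_numpy()
    dd = np.nan_to_num(df["discharge_day_mme"].to_numpy(dtype=float))
    eta = (om["mu_intercept"]
           + om["mu_age_per_decade"] * (age - 60.0) / 10.0
           + om["mu_tobacco_recent"]
           * np.isin(tob, ["past month", "1-12 months"]).astype(float)
           + om["mu_dd_per_10mme"] * np.minimum(dd, 30.0) / 10.0)
    # keep Beta parameters strictly positive for extreme linear predictors
    return np.clip(expit(eta), 1e-9, 1.0 - 1e-9)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a cohort table of patient records.

    Response is drawn from a logistic model in the covariates (intercept
    calibrated to ``response_rate_target`` unless given explicitly);
    consumption is prescription size times a zero-inflated Beta fraction,
    so its support is ``[0, prescribed_mme]`` by construction.  A latent
    ``_true_consumed`` column records the counterfactual consumption of
    every patient for oracle use; ``consumed_mme`` is only populated where
    ``measured`` is true.
    """
    params.validate()
    n = params.n_patients
    rng_cov = _stage_rng(params.seed, "covariates")
    rng_rx = _stage_rng(params.seed, "prescription")
    rng_resp = _stage_rng(params.seed, "response")
    rng_out = _stage_rng(params.seed, "outcome")

    # --- covariates ---
    bin_idx = rng_cov.choice(len(AGE_BINS), size=n, p=_norm(params.age_bin_probs))
    lo = np.array([b[0] for b in AGE_BINS])[bin_idx]
    hi = np.array([b[1] for b in AGE_BINS])[bin_idx]
    age = np.floor(lo + rng_cov.random(n) * (hi - lo)).astype(int)

    sex = rng_cov.choice(SEX_LEVELS, size=n, p=_norm(params.sex_probs))
    race = rng_cov.choice(RACE_LEVELS, size=n, p=_norm(params.race_probs))
    tobacco = rng_cov.choice(TOBACCO_LEVELS, size=n, p=_norm(params.tobacco_probs))
    alcohol = rng_cov.choice(ALCOHOL_LEVELS, size=n, p=_norm(params.alcohol_probs))
    asa = rng_cov.choice([1, 2, 3, 4, 5], size=n, p=_norm(params.asa_probs))
    los = rng_cov.choice(LOS_LEVELS, size=n, p=_norm(params.los_probs))
    months = _month_labels(params.start_month, params.n_months)
    month = rng_cov.choice(months, size=n)

    labels = [p[0] for p in params.procedure_mix]
    typical = {p[0]: p[2] for p in params.procedure_mix}
    proc = rng_cov.choice(labels, size=n, p=_norm([p[1] for p in params.procedure_mix]))

    # --- prescription ---
    prescribed = rng_rx.random(n) >= params.zero_rx_fraction
    typ = np.array([typical[p] for p in proc])
    month_idx = np.array([months.index(m) for m in month])
    drift = 1.0 + params.mme_drift_per_month * (month_idx - (params.n_months - 1) / 2.0)
    drift = np.clip(drift, 0.05, None)
    raw = typ * drift * np.exp(rng_rx.normal(0.0, params.rx_sigma, size=n))
    # round to 5 mg oxycodone pill equivalents (7.5 MME), at least one pill
    mme = np.clip(np.round(raw / 7.5) * 7.5, 7.5, 1200.0)
    prescribed_mme = np.where(prescribed, mme, 0.0)
    n_drugs = np.where(
        prescribed,
        np.where(rng_rx.random(n) < params.multi_drug_prob,
                 rng_rx.integers(2, 4, size=n), 1),
        0,
    )

    dd_zero_p = np.where(prescribed, params.dd_zero_prob_prescribed,
                         params.dd_zero_prob_unprescribed)
    dd_zero = rng_rx.random(n) < dd_zero_p
    dd_pos = np.where(rng_rx.random(n) < 0.78,
                      rng_rx.uniform(1.0, 10.0, size=n),
                      rng_rx.uniform(10.0, 60.0, size=n))
    discharge_day_mme = np.round(np.where(dd_zero, 0.0, dd_pos), 1)

    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "procedure_group": proc,
        "discharge_month": month,
        "age_years": age,
        "sex": sex,
        "race": race,
        "tobacco_use": tobacco,
        "alcohol_use": alcohol,
        "asa_class": asa,
        "los_category": los,
        "preop_assessment": np.ones(n, dtype=int),
        "opioid_drugs_prescribed": n_drugs,
        "prescribed_mme": prescribed_mme,
        "discharge_day_mme": discharge_day_mme,
    })

    # --- response ---
    lp = _response_linear_predictor(df, params.response_coefficients)
    intercept = (params.response_intercept
                 if params.response_intercept is not None
                 else _calibrate_intercept(lp, params.response_rate_target))
    p_resp = expit(intercept + lp)
    responded = rng_resp.random(n) < p_resp
    measured = responded | (prescribed_mme == 0)

    # --- outcome (latent for everyone, truncated to [0, prescribed]) ---
    om = params.outcome_model
    mu = _consumed_fraction_mean(df, om)
    phi = om["precision"]
    frac = rng_out.beta(mu * phi, (1.0 - mu) * phi)
    frac = np.where(rng_out.random(n) < om["zero_prob"], 0.0, frac)
    true_consumed = np.round(prescribed_mme * frac / 7.5) * 7.5
    true_consumed = np.minimum(true_consumed, prescribed_mme)

    df["responded"] = responded.astype(int)
    df["measured"] = measured.astype(int)
    df["consumed_mme"] = np.where(measured, true_consumed, np.nan)
    df["_true_consumed"] = true_consumed
    df["_response_prob"] = p_resp
    return df


def inject_missingness(records: pd.DataFrame, missingness_spec: dict,
                       seed: int) -> pd.DataFrame:
    """Mask covariate cells per spec; never the outcome or flag columns.

    ``columns`` entries are per-column MCAR (or covariate-dependent via
    ``depends_on``/``slope``) rates.  ``blocks`` mask several dependent
    columns together (e.g. everything collected at the preoperative
    assessment) and record the event in a flag column.
    """
    spec = missingness_spec or {}
    named = set(spec.get("columns", {})) | {
        c for b in spec.get("blocks", []) for c in b["columns"]}
    bad = named & PROTECTED_COLUMNS
    if bad:
        raise ValueError(f"missingness spec may not mask outcome/flag columns: {sorted(bad)}")
    missing_cols = named - set(records.columns)
    if missing_cols:
        raise ValueError(f"missingness spec names unknown columns: {sorted(missing_cols)}")

    out = records.copy()
    rng = _stage_rng(seed, "missingness")
    n = len(out)

    for blk in spec.get("blocks", []):
        rate = float(blk["rate"])
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"block {blk.get('name')!r} rate must be in [0, 1]")
        hit = rng.random(n) < rate
        for col in blk["columns"]:
            out[col] = out[col].astype(object)
            out.loc[hit, col] = np.nan
        flag = blk.get("flag_column")
        if flag:
            out.loc[hit, flag] = 0

    for col, cfg in spec.get("columns", {}).items():
        rate = float(cfg["rate"])
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"column {col!r} missing rate must be in [0, 1]")
        if rate == 0.0:
            continue
        if "depends_on" in cfg:
            drv = pd.to_numeric(out[cfg["depends_on"]], errors="coerce").to_numpy(float)
            z = np.nan_to_num((drv - np.nanmean(drv)) / (np.nanstd(drv) + 1e-12))
            p = expit(logit(np.clip(rate, 1e-9, 1 - 1e-9)) + cfg.get("slope", 1.0) * z)
        else:
            p = np.full(n, rate)
        hit = rng.random(n) < p
        if out[col].dtype.kind in "iu" or out[col].dtype == object:
            out[col] = out[col].astype(object)
        out.loc[hit, col] = np.nan
    return out


def true_quantile(params: CohortParams, level: float,
                  subpopulation: str = "prescribed",
                  n_mc: int = 1_000_000) -> float:
    """Ground-truth consumption quantile of the generating process.

    Large-sample Monte Carlo using the latent (pre-nonresponse) consumption
    of a fresh cohort drawn on the oracle sub-stream; inverted-CDF (type-1)
    quantile convention, matching the estimators.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if subpopulation not in ("prescribed", "all"):
        raise ValueError(f"subpopulation must be 'prescribed' or 'all', got {subpopulation!r}")
    oracle_seed = int(_stage_rng(params.seed, "oracle").integers(2**31))
    big = params.replace(n_patients=int(n_mc), seed=oracle_seed)
    df = generate_cohort(big)
    y = df["_true_consumed"].to_numpy()
    if subpopulation == "prescribed":
        y = y[df["prescribed_mme"].to_numpy() > 0]
        if y.size == 0:
            return 0.0
    return float(np.quantile(y, level, method="inverted_cdf"))


# ---------------------------------------------------------------------------
# Compact confounded DGP for estimator validation (double robustness,
# coverage).  One binary covariate, so a logistic model in W is saturated
# (exactly correct) for both the propensity and each threshold regression.
# ---------------------------------------------------------------------------

def simple_confounded_sim(n: int, seed: int, *,
                          p_w: float = 0.5,
                          mu0: float = 3.0,
                          delta: float = 0.9,
                          sigma: float = 0.6,
                          resp_intercept: float = -1.6,
                          resp_slope: float = 2.2) -> pd.DataFrame:
    """Binary confounder W shifts both log-consumption and response odds.

    Y | W ~ LogNormal(mu0 + delta*W, sigma); P(measured | W) =
    expit(resp_intercept + resp_slope*W).  Returns columns ``w``, ``y``
    (NaN where unmeasured), ``measured``, ``_true_y``.
    """
    rng = np.random.Generator(np.random.Philox(key=[seed, 99]))
    w = (rng.random(n) < p_w).astype(float)
    y_true = rng.lognormal(mu0 + delta * w, sigma)
    measured = rng.random(n) < expit(resp_intercept + resp_slope * w)
    return pd.DataFrame({
        "w": w,
        "measured": measured.astype(int),
        "y": np.where(measured, y_true, np.nan),
        "_true_y": y_true,
    })


def simple_sim_true_quantile(level: float, *, p_w: float = 0.5,
                             mu0: float = 3.0, delta: float = 0.9,
                             sigma: float = 0.6) -> float:
    """Exact quantile of the lognormal mixture (no Monte Carlo)."""
    from scipy.stats import norm

    def cdf(y: float) -> float:
        return ((1 - p_w) * norm.cdf((np.log(y) - mu0) / sigma)
                + p_w * norm.cdf((np.log(y) - mu0 - delta) / sigma))

    lo, hi = 1e-6, np.exp(mu0 + delta + 10 * sigma)
    return float(brentq(lambda y: cdf(y) - level, lo, hi, xtol=1e-10))


def write_cohort(df: pd.DataFrame, path: str) -> None:
    """Write as comma-separated text with header (ISO month strings kept)."""
    df.drop(columns=[c for c in df.columns if c.startswith("_")]).to_csv(
        path, index=False)


def read_cohort(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"discharge_month": str})
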