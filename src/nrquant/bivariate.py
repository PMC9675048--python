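"""Nonresponse diagnostics.

Covariate binning, chi-squared association tests for survey response and
consumption measurement (Yates continuity correction on 2x2 tables only),
two-sample Kolmogorov-Smirnov comparisons on raw continuous covariates,
and monthly response/prescription/measurement rate series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BivariateResult", "bin_continuous", "test_association",
           "ks_compare", "temporal_rates", "bivariate_table", "format_p"]


@dataclass
class BivariateResult:
    covariate: str
    levels: list[str]
    level_n: list[int]
    level_rate_pct: list[float]
    statistic: float
    dof: int
    p_value: float
    outcome: str
    zero_rx_excluded: bool

    def __post_init__(self):
        if any(not 0.0 <= r <= 100.0 for r in self.level_rate_pct):
            raise ValueError("rates must be percentages in [0, 100]")


def bin_continuous(values, *, thresholds: list[float] | None = None,
                   quantiles: int | None = None) -> pd.Categorical:
    """Assign values to half-open bins [e_i, e_{i+1}); last bin closed.

    ``thresholds`` gives clinical bin edges (strictly increasing, the last
    edge closes the final bin); values below the first edge land in a
    declared ``<first`` underflow bin with a warning.  ``quantiles=k``
    uses sample k-quantile edges instead.
    """
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    if (thresholds is None) == (quantiles is None):
        raise ValueError("give exactly one of thresholds= or quantiles=")
    if quantiles is not None:
        if quantiles < 2:
            raise ValueError("quantiles must be >= 2")
        finite = v[~np.isnan(v)]
        edges = np.unique(np.quantile(finite, np.linspace(0, 1, quantiles + 1)))
        edges[0], edges[-1] = -np.inf, np.inf
        labels = [f"Q{i + 1}" for i in range(len(edges) - 1)]
        codes = np.searchsorted(edges[1:-1], v, side="right")
        codes = np.where(np.isnan(v), -1, codes)
        return pd.Categorical.from_codes(codes.astype(int), categories=labels)
    edges = list(map(float, thresholds))
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("thresholds must be strictly increasing")
    labels = [_interval_label(a, b) for a, b in zip(edges, edges[1:])]
    underflow = ~np.isnan(v) & (v < edges[0])
    cats = list(labels)
    if underflow.any():
        warnings.warn(f"{int(underflow.sum())} value(s) below first threshold "
                      f"{edges[0]}; assigned to underflow bin")
        cats = [f"<{edges[0]:g}"] + cats
    codes = np.full(len(v), -1, dtype=int)
    for i, (a, b) in enumerate(zip(edges, edges[1:])):
        closed_last = i == len(edges) - 2
        sel = (v >= a) & ((v <= b) if closed_last else (v < b))
        codes[sel] = cats.index(labels[i])
    if underflow.any():
        codes[underflow] = 0
    return pd.Categorical.from_codes(codes, categories=cats)


def _interval_label(a: float, b: float) -> str:
    if float(a).is_integer() and float(b).is_integer():
        return f"{int(a)}-{int(b) - 1}"
    return f"[{a:g}, {b:g})"


def test_association(records: pd.DataFrame, covariate: str, outcome_flag: str,
                     exclude_zero_rx: bool = False) -> BivariateResult:
    """Pearson chi-squared of covariate levels x binary outcome.

    Yates continuity correction iff the table is 2x2.  Records missing the
    covariate are dropped for this test only; ``exclude_zero_rx`` first
    removes zero-prescription records (the measurement column's convention,
    since those are measured by definition).
    """
    if outcome_flag not in ("responded", "measured"):
        raise ValueError("outcome_flag must be 'responded' or 'measured'")
    df = records
    if exclude_zero_rx:
        df = df[df["prescribed_mme"].to_numpy(dtype=float) > 0]
    df = df[df[covariate].notna()]
    if df.empty:
        raise ValueError(f"no records with observed {covariate!r}")
    g = df.groupby(covariate, observed=True, sort=False)[outcome_flag]
    levels = [str(k) for k in g.size().index]
    n = g.size().to_numpy()
    yes = g.sum().to_numpy(dtype=float)
    table = np.column_stack([yes, n - yes])
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty margin (expected count 0)")
    res = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
    if np.any(res.expected_freq < 5):
        warnings.warn(f"expected cell count < 5 in test of {covariate!r}")
    outcome = "response" if outcome_flag == "responded" else "measurement"
    return BivariateResult(
        covariate=covariate, levels=levels,
        level_n=[int(x) for x in n],
        level_rate_pct=[float(100.0 * y / m) for y, m in zip(yes, n)],
        statistic=float(res.statistic), dof=int(res.dof),
        p_value=float(res.pvalue), outcome=outcome,
        zero_rx_excluded=bool(exclude_zero_rx))


def ks_compare(values_group1, values_group2) -> tuple[float, float]:
    """Two-sample K-S statistic sup|ECDF1 - ECDF2| with asymptotic p."""
    a = np.asarray(values_group1, dtype=float)
    b = np.asarray(values_group2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain observed numeric values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def temporal_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per discharge-month response, any-prescription and measurement rates."""
    if "discharge_month" not in records.columns:
        raise KeyError("records lack discharge_month")
    df = records[records["discharge_month"].notna()]
    g = df.groupby("discharge_month", sort=True)
    out = pd.DataFrame({
        "month": list(g.groups),
        "n": g.size().to_numpy(),
        "response_rate": g["responded"].mean().to_numpy(),
        "any_rx_rate": g.apply(
            lambda d: float((d["prescribed_mme"] > 0).mean()),
            include_groups=False).to_numpy(),
        "measured_rate": g["measured"].mean().to_numpy(),
    })
    return out[out["n"] > 0].reset_index(drop=True)


def format_p(p: float) -> str:
    """3-decimal display; values below 0.001 rendered '<0.001'."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def bivariate_table(records: pd.DataFrame,
                    covariates: list[str]) -> pd.DataFrame:
    """Diagnostics table: per covariate level, N, response %, response p,
    measurement %, measurement p (zero-prescription excluded for the
    measurement test, per the known-zero convention)."""
    rows = []
    for cov in covariates:
        r_resp = test_association(records, cov, "responded")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_meas = test_association(records, cov, "measured",
                                      exclude_zero_rx=(cov != "prescribed_mme_bin"))
        meas_rate = {l: r for l, r in zip(r_meas.levels, r_meas.level_rate_pct)}
        for lev, n, rate in zip(r_resp.levels, r_resp.level_n, r_resp.level_rate_pct):
            rows.append({
                "covariate": cov, "level": lev, "n": n,
                "response_pct": round(rate, 1),
                "response_p": format_p(r_resp.p_value),
                "measured_pct": round(meas_rate.get(lev, np.nan), 1),
                "measured_p": format_p(r_meas.p_value),
            })
    return pd.DataFrame(rows)
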