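"""Summary artifacts: correction summaries, reference comparison,
prescription-vs-consumption gaps, rolling quantile trends, report bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrectionSummary", "correction_summary", "compare_reference",
           "prescription_gap", "rolling_quantile_trend", "render_report",
           "load_reference_table"]


@dataclass
class CorrectionSummary:
    level: float
    per_group: pd.DataFrame          # procedure_group, correction_pct (NaN if undefined)
    mean_correction_pct: float
    iqr_correction_pct: tuple[float, float]
    n_undefined: int


def _pivot(estimates: pd.DataFrame, method: str, level: float) -> pd.Series:
    sel = estimates[(estimates["method"] == method)
                    & (np.isclose(estimates["level"], level))]
    return sel.set_index("procedure_group")["point"].sort_index()


def correction_summary(estimates: pd.DataFrame, levels=(0.5, 0.75),
                       signed: bool = False) -> list[CorrectionSummary]:
    """Relative correction of adjusted vs unadjusted per procedure.

    correction = 100 * |adjusted - unadjusted| / unadjusted (absolute by
    default; ``signed=True`` keeps the sign).  Groups with unadjusted 0
    are reported as undefined and excluded from the mean/IQR.
    """
    out = []
    for level in levels:
        adj = _pivot(estimates, "adjusted", level)
        una = _pivot(estimates, "unadjusted", level)
        if set(adj.index) != set(una.index):
            diff = set(adj.index) ^ set(una.index)
            raise ValueError(f"adjusted/unadjusted group mismatch: {sorted(diff)}")
        rel = 100.0 * (adj - una) / una.replace(0.0, np.nan)
        if not signed:
            rel = rel.abs()
        defined = rel.dropna()
        out.append(CorrectionSummary(
            level=level,
            per_group=rel.rename("correction_pct").reset_index(),
            mean_correction_pct=float(defined.mean()) if len(defined) else np.nan,
            iqr_correction_pct=(float(defined.quantile(0.25)),
                                float(defined.quantile(0.75)))
            if len(defined) else (np.nan, np.nan),
            n_undefined=int(rel.isna().sum())))
    return out


def compare_reference(estimates: pd.DataFrame, reference: pd.DataFrame,
                      levels=(0.5, 0.75)) -> pd.DataFrame:
    """Per level: how many groups the adjustment moved closer to the
    reference survey.  Ties count as 'unchanged'; groups absent from the
    reference are excluded with a notice column."""
    rows = []
    ref = reference.set_index("procedure_group")
    for level in levels:
        adj = _pivot(estimates, "adjusted", level)
        una = _pivot(estimates, "unadjusted", level)
        col = "median_mme" if np.isclose(level, 0.5) else "p75_mme"
        closer = farther = unchanged = 0
        excluded = []
        for g in adj.index:
            if g not in ref.index:
                excluded.append(g)
                continue
            da = abs(adj[g] - ref.loc[g, col])
            du = abs(una[g] - ref.loc[g, col])
            if da < du:
                closer += 1
            elif da > du:
                farther += 1
            else:
                unchanged += 1
        compared = closer + farther + unchanged
        rows.append({"level": level, "closer": closer, "farther": farther,
                     "unchanged": unchanged, "n_compared": compared,
                     "tally": f"{closer}/{compared}",
                     "excluded_groups": ";".join(map(str, excluded))})
    return pd.DataFrame(rows)


def prescription_gap(records: pd.DataFrame,
                     groups: list[str] | None = None) -> pd.DataFrame:
    """Quantile ratios of consumption to prescription among prescribed
    patients with measured consumption, per group and pooled.

    ratio = 100 * quantile(consumed) / quantile(prescribed);
    unconsumed share = 100 - ratio.
    """
    df = records[(records["prescribed_mme"].to_numpy(dtype=float) > 0)
                 & (records["measured"].to_numpy(dtype=float) > 0)]
    if groups is not None:
        df = df[df["procedure_group"].isin(groups)]
    rows = []
    frames = [("pooled", df)] + [(g, d) for g, d in
                                 df.groupby("procedure_group", sort=True)]
    for name, d in frames:
        if d.empty:
            continue
        cons = d["consumed_mme"].to_numpy(dtype=float)
        rx = d["prescribed_mme"].to_numpy(dtype=float)
        row = {"group": name, "n": len(d)}
        for label, q in (("median", 0.5), ("p75", 0.75)):
            qc = float(np.quantile(cons, q, method="inverted_cdf"))
            qr = float(np.quantile(rx, q, method="inverted_cdf"))
            if qr == 0:
                raise ValueError(f"zero {label} prescription in group {name!r}")
            ratio = 100.0 * qc / qr
            row[f"{label}_ratio_pct"] = round(ratio, 1)
            row[f"{label}_unconsumed_pct"] = round(100.0 - ratio, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def rolling_quantile_trend(records: pd.DataFrame, group: str, level: float,
                           window_months: int = 3, min_n: int = 10
                           ) -> pd.DataFrame:
    """Trailing-window empirical quantile of measured consumption per
    window-end month for one procedure group."""
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    df = records[(records["procedure_group"] == group)
                 & (records["measured"].to_numpy(dtype=float) > 0)]
    if df.empty:
        raise ValueError(f"unknown or empty procedure group {group!r}")
    months = sorted(records["discharge_month"].dropna().unique())
    rows = []
    for i, end in enumerate(months):
        window = months[max(0, i - window_months + 1): i + 1]
        vals = df[df["discharge_month"].isin(window)]["consumed_mme"]
        vals = vals.dropna().to_numpy(dtype=float)
        if vals.size < min_n:
            continue
        rows.append({"month": end, "n": int(vals.size),
                     "quantile_mme": round(float(
                         np.quantile(vals, level, method="inverted_cdf")), 1)})
    return pd.DataFrame(rows, columns=["month", "n", "quantile_mme"])


def load_reference_table(path: str) -> pd.DataFrame:
    """Reference survey quantiles: procedure_group, median_mme, p75_mme, n."""
    ref = pd.read_csv(path)
    need = {"procedure_group", "median_mme", "p75_mme", "n"}
    if not need <= set(ref.columns):
        raise ValueError(f"reference table must have columns {sorted(need)}")
    if (ref["median_mme"] < 0).any() or (ref["p75_mme"] < ref["median_mme"]).any():
        raise ValueError("reference table violates 0 <= median <= p75")
    return ref


def _round_mme(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f" and c != "level":
            out[c] = out[c].round(1)
    return out


def render_report(outdir: str, *, cohort_summary: pd.DataFrame,
                  bivariate_table: pd.DataFrame, rate_series: pd.DataFrame,
                  estimates: pd.DataFrame, trend: pd.DataFrame,
                  corrections: list[CorrectionSummary],
                  manifest: dict) -> list[str]:
    """Write the seven bundle files; returns their paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = []

    def write_csv(name, df):
        p = os.path.join(outdir, name)
        _round_mme(df).to_csv(p, index=False)
        paths.append(p)

    write_csv("cohort_summary.csv", cohort_summary)
    write_csv("bivariate.csv", bivariate_table)
    write_csv("rates_by_month.csv", rate_series)
    write_csv("estimates.csv", estimates)
    write_csv("quantile_trend.csv", trend)
    p = os.path.join(outdir, "correction_summary.json")
    with open(p, "w") as fh:
        json.dump([{
            "level": c.level,
            "mean_correction_pct": None if np.isnan(c.mean_correction_pct)
            else round(c.mean_correction_pct, 1),
            "iqr_correction_pct": [None if np.isnan(v) else round(v, 1)
                                   for v in c.iqr_correction_pct],
            "n_undefined": c.n_undefined,
            "per_group": {r["procedure_group"]:
                          None if np.isnan(r["correction_pct"])
                          else round(r["correction_pct"], 1)
                          for _, r in c.per_group.iterrows()},
        } for c in corrections], fh, indent=2)
    paths.append(p)
    p = os.path.join(outdir, "manifest.json")
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths.append(p)
    return paths


def cohort_summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by population (all / responders / measured)."""
    pops = {
        "full_study": records,
        "responders": records[records["responded"] == 1],
        "measured": records[records["measured"] == 1],
    }
    cat_cols = ["race", "tobacco_use", "los_category", "sex",
                "opioid_drugs_prescribed"]
    rows = []
    for col in cat_cols:
        if col not in records.columns:
            continue
        levels = records[col].dropna().unique()
        for lev in sorted(map(str, levels)):
            row = {"characteristic": col, "value": lev}
            for pname, pdf in pops.items():
                s = pdf[col].dropna().astype(str)
                row[f"{pname}_pct"] = round(100.0 * (s == lev).mean(), 1) \
                    if len(s) else np.nan
            rows.append(row)
    for pname, pdf in pops.items():
        rows.append({"characteristic": "n", "value": "count",
                     f"{pname}_pct": len(pdf)})
    return pd.DataFrame(rows)
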