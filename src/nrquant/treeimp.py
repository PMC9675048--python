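"""Variable importance via tree-split counts.

Random-forest impurity screening keeps the top-k whole variables (before
any indicator encoding); the tally ensemble then counts how often each
variable is used in decision-tree splits.  The tally ensemble is the
sum-of-trees sampler when requested (counts aggregated over retained
posterior draws) or a random forest by default; indicator columns are
aggregated back to their parent categorical variable before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["ImportanceTable", "rf_screen", "split_count_importance",
           "importance_analysis", "flag_confounders"]

RAW_VARIABLES = [
    "age_years", "sex", "race", "tobacco_use", "alcohol_use", "asa_class",
    "los_category", "preop_assessment", "opioid_drugs_prescribed",
    "prescribed_mme", "discharge_day_mme", "procedure_group",
]


@dataclass
class ImportanceTable:
    target: str                      # 'measurement' | 'consumption'
    table: pd.DataFrame              # variable, share, rank
    ensemble_type: str
    screened: list[str]

    def __post_init__(self):
        s = self.table["share"].to_numpy()
        if (s < 0).any() or not np.isclose(s.sum(), 1.0, atol=1e-8):
            raise ValueError("split-count shares must be >= 0 and sum to 1")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..k")

    def top(self, k: int) -> list[str]:
        return list(self.table.nsmallest(k, "rank")["variable"])


def _ordinal_encode(records: pd.DataFrame, variables: list[str]) -> np.ndarray:
    """Whole-variable numeric encoding (categoricals as level codes) so
    screening sees each variable as a single column."""
    cols = []
    for v in variables:
        s = records[v]
        if s.dtype == object or str(s.dtype) == "category":
            codes = pd.Categorical(s).codes.astype(float)
            codes[codes < 0] = np.nan
            cols.append(codes)
        else:
            cols.append(pd.to_numeric(s, errors="coerce").to_numpy(dtype=float))
    X = np.column_stack(cols)
    # trees need complete data; fill remaining holes with column medians
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmedian(col) if not np.all(np.isnan(col)) else 0.0
    return X


def rf_screen(records: pd.DataFrame, y: np.ndarray, variables: list[str],
              k: int, *, task: str, seed: int = 0) -> list[str]:
    """Top-k variables by random-forest impurity importance."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(variables):
        raise ValueError(f"k={k} exceeds the {len(variables)} variables")
    X = _ordinal_encode(records, variables)
    est = (RandomForestClassifier if task == "binary" else RandomForestRegressor)(
        n_estimators=300, min_samples_leaf=5, random_state=seed, n_jobs=1)
    est.fit(X, np.asarray(y))
    order = np.argsort(est.feature_importances_)[::-1][:k]
    return [variables[i] for i in sorted(order)]


def split_count_importance(ensemble, variables: list[str],
                           parents: dict[str, str] | None = None,
                           target: str = "measurement",
                           ensemble_type: str = "random_forest",
                           screened: list[str] | None = None
                           ) -> ImportanceTable:
    """Share of decision-tree splits attributed to each variable.

    Accepts a fitted sklearn forest (per-tree split features) or the
    sum-of-trees sampler (``split_counts_`` aggregated over retained
    posterior draws).  ``parents`` maps encoded column names back to their
    categorical variable; counts are pooled per parent before ranking.
    """
    counts = np.zeros(len(variables))
    if hasattr(ensemble, "split_counts_") and ensemble.split_counts_ is not None:
        counts += np.asarray(ensemble.split_counts_, dtype=float)
    elif hasattr(ensemble, "estimators_"):
        for tree in ensemble.estimators_:
            feat = tree.tree_.feature
            for f in feat[feat >= 0]:
                counts[f] += 1
    else:
        raise TypeError("ensemble exposes neither split_counts_ nor estimators_")
    if counts.sum() == 0:
        raise ValueError("ensemble contains zero splits")
    if parents:
        agg: dict[str, float] = {}
        for name, c in zip(variables, counts):
            agg[parents.get(name, name)] = agg.get(parents.get(name, name), 0.0) + c
        names, counts = list(agg), np.array(list(agg.values()))
    else:
        names = list(variables)
    share = counts / counts.sum()
    order = np.argsort(-share, kind="stable")
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    table = pd.DataFrame({"variable": names, "share": share, "rank": rank}
                         ).sort_values("rank").reset_index(drop=True)
    return ImportanceTable(target, table, ensemble_type,
                           screened if screened is not None else list(names))


def _tally_ensemble(X: np.ndarray, y: np.ndarray, task: str, kind: str,
                    seed: int):
    if kind == "bart":
        from .sumtrees import BartClassifier, BartRegressor
        est = (BartClassifier if task == "binary" else BartRegressor)(
            n_trees=50, n_burn=100, n_draw=200, seed=seed)
        return est.fit(X, y)
    # shallow trees control the cardinality bias of raw split counts:
    # deep trees shower spurious splits on continuous variables
    est = (RandomForestClassifier if task == "binary" else RandomForestRegressor)(
        n_estimators=500, max_depth=4, random_state=seed, n_jobs=1)
    return est.fit(X, y)


def importance_analysis(records: pd.DataFrame, *, k: int = 25, seed: int = 0,
                        ensemble: str = "random_forest",
                        variables: list[str] | None = None
                        ) -> tuple[ImportanceTable, ImportanceTable]:
    """Two rankings among patients prescribed opioids.

    (a) 'measurement': which variables predict whether consumption could
    be measured; (b) 'consumption': which variables predict consumed MMEs
    among measured prescribed patients.  Both screen to the top-k whole
    variables first, then tally splits.
    """
    variables = variables or [v for v in RAW_VARIABLES if v in records.columns]
    presc = records[records["prescribed_mme"].to_numpy(dtype=float) > 0]
    meas = presc[presc["measured"].to_numpy(dtype=float) > 0]
    if len(meas) < 50:
        raise ValueError(f"only {len(meas)} prescribed-measured records; need >= 50")
    k = min(k, len(variables))

    tables = []
    for target, frame, yv, task in (
            ("measurement", presc, presc["measured"].to_numpy(dtype=float), "binary"),
            ("consumption", meas, meas["consumed_mme"].to_numpy(dtype=float),
             "continuous")):
        screened = rf_screen(frame, yv, variables, k, task=task, seed=seed)
        X = _ordinal_encode(frame, screened)
        est = _tally_ensemble(X, yv, task, ensemble, seed)
        tables.append(split_count_importance(est, screened, target=target,
                                             ensemble_type=ensemble,
                                             screened=screened))
    return tables[0], tables[1]


def flag_confounders(measurement: ImportanceTable,
                     consumption: ImportanceTable, top: int = 5) -> list[str]:
    """Variables ranking in the top of BOTH tables: observed confounders
    indicating likely nonresponse bias."""
    return sorted(set(measurement.top(top)) & set(consumption.top(top)))
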