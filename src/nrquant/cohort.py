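"""Analysis-cohort assembly.

Eligibility filtering, pill-to-MME conversion, the known-zero rule for
patients with no opioid prescription, and construction of the numeric
design matrix with an explicit missingness mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EligibilityRule",
    "CovariateMatrix",
    "DEFAULT_MME_FACTORS",
    "default_predictor_spec",
    "apply_eligibility",
    "pills_to_mme",
    "assign_known_zeros",
    "build_design_matrix",
]

# Published CDC equianalgesic factors (oral); overridable via config.
# opioid name -> morphine-equivalence factor per mg
DEFAULT_MME_FACTORS: dict[str, float] = {
    "morphine": 1.0,
    "oxycodone": 1.5,
    "hydrocodone": 1.0,
    "hydromorphone": 4.0,
    "oxymorphone": 3.0,
    "codeine": 0.15,
    "tramadol": 0.1,
    "tapentadol": 0.4,
}

_OPS = {
    ">=": lambda s, v: s >= v,
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    "<": lambda s, v: s < v,
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
    "in": lambda s, v: s.isin(v),
    "not_in": lambda s, v: ~s.isin(v),
}


@dataclass
class EligibilityRule:
    """A single keep-if predicate, applied in declared order.

    ``field op value`` must hold for a record to be retained; e.g.
    ``EligibilityRule("adult", "age_years", ">=", 18)``.
    """

    rule_id: str
    field: str
    op: str
    value: object
    description: str = ""

    def mask(self, records: pd.DataFrame) -> pd.Series:
        if self.field not in records.columns:
            raise KeyError(
                f"eligibility rule {self.rule_id!r} references absent field {self.field!r}")
        if self.op not in _OPS:
            raise ValueError(f"unknown eligibility op {self.op!r}")
        keep = _OPS[self.op](records[self.field], self.value)
        return keep.fillna(False).astype(bool)


def apply_eligibility(records: pd.DataFrame, rules: list[EligibilityRule]
                      ) -> tuple[pd.DataFrame, list[dict]]:
    """Filter sequentially; report per-rule exclusion counts in order."""
    out = records
    report = []
    for rule in rules:
        keep = rule.mask(out)
        excluded = int((~keep).sum())
        report.append({
            "rule_id": rule.rule_id,
            "field": rule.field,
            "op": rule.op,
            "value": rule.value,
            "excluded": excluded,
            "remaining": int(keep.sum()),
        })
        out = out.loc[keep]
    return out.copy(), report


def pills_to_mme(pill_count: float, strength_mg: float, factor: float) -> float:
    """pill_count x mg strength x morphine-equivalence factor."""
    if pill_count < 0 or strength_mg < 0 or factor < 0:
        raise ValueError("pills_to_mme inputs must be non-negative")
    return float(pill_count) * float(strength_mg) * float(factor)


def assign_known_zeros(records: pd.DataFrame) -> pd.DataFrame:
    """Patients with no opioid prescription are measured zero-consumers.

    Idempotent.  A zero-prescription record carrying a nonzero reported
    consumption is inconsistent: the report is kept, flagged in the
    ``consumption_inconsistent`` column, and a warning is raised.
    """
    if records["prescribed_mme"].isna().any():
        raise ValueError("prescribed_mme must be present for all records")
    out = records.copy()
    zero_rx = out["prescribed_mme"].to_numpy(dtype=float) == 0.0
    consumed = out["consumed_mme"].to_numpy(dtype=float)
    inconsistent = zero_rx & ~np.isnan(consumed) & (consumed > 0)
    if inconsistent.any():
        warnings.warn(
            f"{int(inconsistent.sum())} zero-prescription record(s) report nonzero "
            "consumption; kept as reported and flagged")
        out["consumption_inconsistent"] = inconsistent.astype(int)
    fill = zero_rx & ~inconsistent
    out.loc[fill, "consumed_mme"] = 0.0
    out.loc[zero_rx, "measured"] = 1
    return out


@dataclass
class CovariateMatrix:
    """Numeric design matrix with column metadata and a missingness mask.

    ``values`` holds NaN at masked cells; ``mask`` is True where missing.
    ``parents`` maps indicator columns back to the categorical variable
    they encode, for importance aggregation.
    """

    values: np.ndarray
    mask: np.ndarray
    columns: list[str]
    kinds: list[str]
    row_ids: np.ndarray
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column names do not match value width")
        if not np.array_equal(np.isnan(self.values), self.mask):
            raise ValueError("mask and values are not congruent (NaN <-> masked)")
        for j, kind in enumerate(self.kinds):
            if kind == "indicator":
                col = self.values[~self.mask[:, j], j]
                if not np.all(np.isin(col, (0.0, 1.0))):
                    raise ValueError(
                        f"indicator column {self.columns[j]!r} has non-binary values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "CovariateMatrix":
        return CovariateMatrix(self.values.copy(), self.mask.copy(),
                               list(self.columns), list(self.kinds),
                               self.row_ids.copy(), dict(self.parents))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def default_predictor_spec() -> list[dict]:
    """Predictor encoding for the synthetic cohort schema."""
    return [
        {"name": "age_years", "kind": "numeric"},
        {"name": "sex", "kind": "categorical",
         "levels": ["female", "male"], "reference": "female"},
        {"name": "race", "kind": "categorical",
         "levels": ["White", "Asian", "Black", "Hispanic", "Other"],
         "reference": "White"},
        {"name": "tobacco_use", "kind": "categorical",
         "levels": ["never", "past month", "1-12 months", "history"],
         "reference": "never"},
        {"name": "alcohol_use", "kind": "categorical",
         "levels": ["never", "occasionally", "daily"],
         "reference": "occasionally"},
        {"name": "asa_class", "kind": "numeric"},
        {"name": "los_category", "kind": "categorical",
         "levels": ["outpatient", "1-2 days", "3-15 days"],
         "reference": "outpatient"},
        {"name": "preop_assessment", "kind": "numeric"},
        {"name": "opioid_drugs_prescribed", "kind": "numeric"},
        {"name": "prescribed_mme", "kind": "numeric"},
        {"name": "discharge_day_mme", "kind": "numeric"},
    ]


def build_design_matrix(records: pd.DataFrame,
                        predictor_spec: list[dict]) -> CovariateMatrix:
    """Encode predictors into a CovariateMatrix.

    Numeric predictors pass through; categoricals become k-1 indicator
    columns against the stated reference level.  Missing cells stay
    masked (NaN), never zero-filled; a missing categorical masks all of
    its indicator columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    parents: dict[str, str] = {}
    n = len(records)
    for spec in predictor_spec:
        name = spec["name"]
        if name not in records.columns:
            raise KeyError(f"predictor {name!r} not in records")
        if spec["kind"] == "numeric":
            v = pd.to_numeric(records[name], errors="coerce").to_numpy(dtype=float)
            cols.append(v)
            names.append(name)
            kinds.append("numeric")
        elif spec["kind"] == "categorical":
            levels = list(spec["levels"])
            ref = spec.get("reference", levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {name!r}")
            raw = records[name]
            observed = raw.notna().to_numpy()
            vals = raw.astype(object).to_numpy()
            unseen = set(vals[observed]) - set(levels) - {np.nan}
            # categorical columns round-trip through CSV as strings
            unseen -= {str(l) for l in levels}
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(map(str, unseen))} in column {name!r}")
            str_vals = np.array([str(v) for v in vals], dtype=object)
            for lev in levels:
                if lev == ref:
                    continue
                ind = np.where(observed, (str_vals == str(lev)).astype(float), np.nan)
                cols.append(ind)
                cname = f"{name}={lev}"
                names.append(cname)
                kinds.append("indicator")
                parents[cname] = name
        else:
            raise ValueError(f"unknown predictor kind {spec['kind']!r} for {name!r}")
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    mask = np.isnan(values)
    row_ids = (records["patient_id"].to_numpy()
               if "patient_id" in records.columns else np.arange(n))
    return CovariateMatrix(values, mask, names, kinds, row_ids, parents)
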