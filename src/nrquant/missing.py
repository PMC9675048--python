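"""Generalized low-rank model imputation and missingness indicators.

Quadratic-loss GLRM fit by alternating ridge least squares over observed
cells of the column-standardized matrix.  Masked cells are filled with the
de-standardized factor product; indicator columns are clipped to [0, 1].
Missingness indicators are appended as predictors after removing perfectly
collinear (identical-pattern) and constant indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CovariateMatrix

__all__ = ["GlrmFit", "fit_glrm", "impute", "add_missingness_indicators",
           "column_mean_impute"]


@dataclass
class GlrmFit:
    rank: int
    row_factors: np.ndarray        # n x k
    col_factors: np.ndarray        # k x d
    offsets: np.ndarray            # per-column mean over observed cells
    scales: np.ndarray             # per-column std over observed cells
    reg_weight: float
    converged: bool
    n_iter: int
    objective: float
    objective_path: list[float]
    columns: list[str]


def _objective(Xs: np.ndarray, obs: np.ndarray, U: np.ndarray, V: np.ndarray,
               lam: float) -> float:
    R = (Xs - U @ V)
    return float(np.sum(R[obs] ** 2) + lam * (np.sum(U ** 2) + np.sum(V ** 2)))


def fit_glrm(X: CovariateMatrix, rank: int = 5, reg_weight: float = 1e-3,
             seed: int = 0, tol: float = 1e-6, max_iter: int = 500) -> GlrmFit:
    """Alternating minimization of the observed-cell quadratic loss.

    Objective: sum over observed cells of (x - u.v)^2 on standardized
    columns, plus ``reg_weight`` times the squared Frobenius norms of both
    factors.  Stops when the relative objective change drops below ``tol``.
    Deterministic for a given seed.
    """
    n, d = X.shape
    if not 1 <= rank <= min(n, d):
        raise ValueError(f"rank must be in [1, min(n, d)={min(n, d)}], got {rank}")
    obs = ~X.mask
    dead = np.where(obs.sum(axis=0) == 0)[0]
    if dead.size:
        raise ValueError(
            f"column(s) with zero observed cells: {[X.columns[j] for j in dead]}")

    offsets = np.array([X.values[obs[:, j], j].mean() for j in range(d)])
    scales = np.array([X.values[obs[:, j], j].std() for j in range(d)])
    scales[scales < 1e-12] = 1.0
    Xs = (X.values - offsets) / scales
    Xs = np.nan_to_num(Xs)

    rng = np.random.Generator(np.random.Philox(key=[seed, 7]))
    U = rng.normal(0.0, 0.1, size=(n, rank))
    V = rng.normal(0.0, 0.1, size=(rank, d))
    lam = float(reg_weight)
    eye = np.eye(rank)

    path = [_objective(Xs, obs, U, V, lam)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # row update: ridge LS per row over its observed columns
        for i in range(n):
            ji = obs[i]
            if not ji.any():
                U[i] = 0.0  # rank-0 behaviour: fully-missing row -> offsets
                continue
            Vi = V[:, ji]
            U[i] = np.linalg.solve(Vi @ Vi.T + lam * eye, Vi @ Xs[i, ji])
        for j in range(d):
            ij = obs[:, j]
            Uj = U[ij]
            V[:, j] = np.linalg.solve(Uj.T @ Uj + lam * eye, Uj.T @ Xs[ij, j])
        path.append(_objective(Xs, obs, U, V, lam))
        prev, cur = path[-2], path[-1]
        if prev - cur < tol * max(prev, 1e-12):
            converged = True
            break

    if not np.all(np.isfinite(U)) or not np.all(np.isfinite(V)):
        raise FloatingPointError("GLRM factors diverged (non-finite)")
    return GlrmFit(rank, U, V, offsets, scales, lam, converged, it,
                   path[-1], path, list(X.columns))


def impute(X: CovariateMatrix, fit: GlrmFit) -> CovariateMatrix:
    """Fill masked cells with the de-standardized factor product.

    Observed cells are untouched.  Indicator-kind columns are clipped to
    [0, 1] after de-standardization.
    """
    if list(X.columns) != fit.columns or X.shape[0] != fit.row_factors.shape[0]:
        raise ValueError("fit was not trained on this matrix")
    recon = fit.row_factors @ fit.col_factors
    recon = recon * fit.scales + fit.offsets
    values = np.where(X.mask, recon, X.values)
    for j, kind in enumerate(X.kinds):
        if kind == "indicator":
            values[:, j] = np.clip(values[:, j], 0.0, 1.0)
    out = X.copy()
    out.values = values
    out.mask = np.zeros_like(X.mask)
    return out


def column_mean_impute(X: CovariateMatrix) -> CovariateMatrix:
    """Baseline imputer: observed-cell column means."""
    values = X.values.copy()
    for j in range(X.shape[1]):
        obs = ~X.mask[:, j]
        if not obs.any():
            raise ValueError(f"column {X.columns[j]!r} has zero observed cells")
        values[X.mask[:, j], j] = values[obs, j].mean()
    out = X.copy()
    out.values = values
    out.mask = np.zeros_like(X.mask)
    return out


def add_missingness_indicators(X: CovariateMatrix) -> CovariateMatrix:
    """Append one {0,1} was-missing column per originally-missing column.

    Among indicators with byte-identical missingness patterns only the
    first (column order) is kept; constant indicators are dropped.  The
    retained set therefore has no duplicated columns and no intercept-
    collinear column.
    """
    n, d = X.shape
    seen: dict[bytes, str] = {}
    add_cols, add_names = [], []
    for j in range(d):
        pat = X.mask[:, j]
        if not pat.any() or pat.all():
            continue  # constant indicator: carries no information
        key = np.packbits(pat).tobytes()
        if key in seen:
            continue
        seen[key] = X.columns[j]
        add_cols.append(pat.astype(float))
        add_names.append(f"miss:{X.columns[j]}")
    if not add_cols:
        return X.copy()
    values = np.column_stack([X.values] + add_cols)
    mask = np.column_stack([X.mask, np.zeros((n, len(add_cols)), dtype=bool)])
    out = CovariateMatrix(values, mask, list(X.columns) + add_names,
                          list(X.kinds) + ["indicator"] * len(add_cols),
                          X.row_ids.copy(), dict(X.parents))
    return out


def imputation_report(X: CovariateMatrix, completed: CovariateMatrix) -> dict:
    rates = X.mask.mean(axis=0)
    return {
        "per_column_missing_rate": {c: float(r) for c, r in zip(X.columns, rates)},
        "retained_indicators": [c for c in completed.columns if c.startswith("miss:")],
    }
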