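"""Cross-validated convex stacking over a learner library.

The library mirrors the study's: outcome mean, stratification on
prescribed/discharge-day MME bins, ordinary least squares, lasso and
random forest (each screened two ways), with Bayesian additive regression
trees added for the binary (propensity) task.  Screening keeps predictors
whose Pearson correlation with the target is significant at p < alpha.
Convex weights minimize cross-validated squared error (continuous) or
Bernoulli log-loss (binary) on the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["LearnerSpec", "EnsembleModel", "default_library",
           "screen_correlation", "cv_stack", "predict_ensemble"]

_CLIP = 1e-6

RX_BIN_EDGES = [0.0, 1.0, 100.0, 300.0, np.inf]       # 0 / 1-99 / 100-299 / 300+
DD_BIN_EDGES = [0.0, 1.0, 10.0 + 1e-9, np.inf]        # 0 / 1-10 / >10


@dataclass(frozen=True)
class LearnerSpec:
    learner_id: str
    family: str                     # mean|stratified|linear|lasso|random_forest|bart
    screen: str = "all"             # "all" or "corr"
    alpha: float = 0.1              # screening p-value threshold
    hyperparameters: tuple = ()     # frozen (key, value) pairs

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


def default_library(task: str, include_bart: bool = True) -> list[LearnerSpec]:
    """The study's libraries: 8 entries (continuous) / 10 (binary).

    The five non-trivial learner families are each tested with all
    predictors and with the correlation-screened subset; mean and the
    MME-bin stratifier are unscreened.
    """
    if task not in ("continuous", "binary"):
        raise ValueError(f"unknown task {task!r}")
    lib = [
        LearnerSpec("mean", "mean"),
        LearnerSpec("stratified_mme", "stratified"),
        LearnerSpec("ols_all", "linear", "all"),
        LearnerSpec("ols_screened", "linear", "corr"),
        LearnerSpec("lasso_all", "lasso", "all"),
        LearnerSpec("lasso_screened", "lasso", "corr"),
        LearnerSpec("rf_all", "random_forest", "all"),
        LearnerSpec("rf_screened", "random_forest", "corr"),
    ]
    if task == "binary" and include_bart:
        lib += [
            LearnerSpec("bart_all", "bart", "all"),
            LearnerSpec("bart_screened", "bart", "corr"),
        ]
    return lib


def screen_correlation(X: np.ndarray, y: np.ndarray, alpha: float = 0.1
                       ) -> np.ndarray:
    """Indices of columns Pearson-correlated with y at p < alpha.

    Constant columns are excluded with a warning (correlation undefined).
    If nothing passes, the single smallest-p column is kept so the design
    is never empty.
    """
    X = np.asarray(X, dtype=float)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    pvals = np.full(X.shape[1], np.inf)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(f"constant column {j} excluded from screening")
            continue
        pvals[j] = pearsonr(col, y).pvalue
    keep = np.where(pvals < alpha)[0]
    if keep.size == 0:
        keep = np.array([int(np.argmin(pvals))])
    return keep


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

class _MeanLearner:
    def fit(self, X, y):
        self.c = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.c)


class _StratifiedLearner:
    """Mean outcome within (prescribed-MME bin x discharge-day-MME bin);
    empty or unseen stratum falls back to the grand mean."""

    def __init__(self, rx_idx: int | None, dd_idx: int | None):
        self.rx_idx, self.dd_idx = rx_idx, dd_idx

    def _strata(self, X):
        rx = np.digitize(X[:, self.rx_idx], RX_BIN_EDGES[1:-1], right=False)
        dd = np.digitize(X[:, self.dd_idx], DD_BIN_EDGES[1:-1], right=False)
        return rx * 10 + dd

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.grand = float(y.mean())
        self.table = {}
        if self.rx_idx is None or self.dd_idx is None:
            return self
        s = self._strata(np.asarray(X, dtype=float))
        for key in np.unique(s):
            self.table[int(key)] = float(y[s == key].mean())
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.rx_idx is None or self.dd_idx is None:
            return np.full(X.shape[0], self.grand)
        s = self._strata(X)
        return np.array([self.table.get(int(k), self.grand) for k in s])


class _SkWrapper:
    """Adapts an sklearn estimator; classifiers predict P(y=1)."""

    def __init__(self, est, binary: bool):
        self.est, self.binary = est, binary

    def fit(self, X, y):
        self.est.fit(X, y)
        return self

    def predict(self, X):
        if self.binary and hasattr(self.est, "predict_proba"):
            proba = self.est.predict_proba(X)
            cls = list(getattr(self.est, "classes_", [0, 1]))
            return proba[:, cls.index(1)] if 1 in cls else np.zeros(len(X))
        return np.asarray(self.est.predict(X), dtype=float)


def _make_base(spec: LearnerSpec, task: str, seed: int,
               columns: list[str] | None):
    binary = task == "binary"
    hp = spec.hp
    if spec.family == "mean":
        return _MeanLearner()
    if spec.family == "stratified":
        def find(name):
            if columns is None:
                return None
            if name in columns:
                return columns.index(name)
            tail = [j for j, c in enumerate(columns) if c.endswith(":" + name)]
            return tail[0] if tail else None

        rx = find(hp.get("rx_col", "prescribed_mme"))
        dd = find(hp.get("dd_col", "discharge_day_mme"))
        if rx is None or dd is None:
            warnings.warn("stratified learner missing its MME columns; "
                          "falls back to the grand mean")
        return _StratifiedLearner(rx, dd)
    if spec.family == "linear":
        est = (LogisticRegression(C=np.inf, max_iter=2000) if binary
               else LinearRegression())
        return _SkWrapper(est, binary)
    if spec.family == "lasso":
        est = (LogisticRegression(l1_ratio=1, C=hp.get("C", 1.0),
                                  solver="liblinear", max_iter=2000) if binary
               else Lasso(alpha=hp.get("alpha", 0.01), max_iter=5000))
        return _SkWrapper(est, binary)
    if spec.family == "random_forest":
        kw = dict(n_estimators=hp.get("n_estimators", 200),
                  min_samples_leaf=hp.get("min_samples_leaf", 5),
                  random_state=seed, n_jobs=1)
        est = RandomForestClassifier(**kw) if binary else RandomForestRegressor(**kw)
        return _SkWrapper(est, binary)
    if spec.family == "bart":
        from .sumtrees import BartClassifier, BartRegressor
        kw = dict(n_trees=hp.get("n_trees", 20), n_burn=hp.get("n_burn", 50),
                  n_draw=hp.get("n_draw", 50), seed=seed)
        est = BartClassifier(**kw) if binary else BartRegressor(**kw)
        return _SkWrapper(est, binary)
    raise ValueError(f"unknown learner family {spec.family!r}")


class _FittedLearner:
    """A base learner plus its screened column subset."""

    def __init__(self, spec: LearnerSpec, task: str, seed: int,
                 columns: list[str] | None):
        self.spec = spec
        self.task = task
        self.seed = seed
        self.columns = columns
        self.keep: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.spec.screen == "corr":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.keep = screen_correlation(X, y, self.spec.alpha)
            cols = ([self.columns[j] for j in self.keep]
                    if self.columns is not None else None)
            Xs = X[:, self.keep]
        else:
            cols, Xs = self.columns, X
        self.base = _make_base(self.spec, self.task, self.seed, cols)
        self.base.fit(Xs, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.keep is not None:
            X = X[:, self.keep]
        return np.asarray(self.base.predict(X), dtype=float)


@dataclass
class EnsembleModel:
    library: list[LearnerSpec]
    task: str
    columns: list[str] | None
    folds: np.ndarray
    cv_risks: np.ndarray
    weights: np.ndarray
    learners: list[_FittedLearner]
    ensemble_cv_risk: float
    seed: int = 0
    notes: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "task": self.task,
            "seed": int(self.seed),
            "library": [
                {"learner_id": s.learner_id, "family": s.family,
                 "screen": s.screen, "alpha": s.alpha,
                 "hyperparameters": dict(s.hyperparameters),
                 "cv_risk": float(r), "weight": float(w)}
                for s, r, w in zip(self.library, self.cv_risks, self.weights)
            ],
            "ensemble_cv_risk": float(self.ensemble_cv_risk),
            "notes": list(self.notes),
        }


def _risk(pred: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "binary":
        p = np.clip(pred, _CLIP, 1.0 - _CLIP)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((y - pred) ** 2))


def _simplex_weights(Z: np.ndarray, y: np.ndarray, task: str,
                     usable: np.ndarray) -> np.ndarray:
    """Convex weights minimizing the cross-validated risk of the blend.

    Initialized at the best single usable learner, so the solution risk
    never exceeds the best single risk; ties break toward earlier library
    order via argmin.
    """
    L = Z.shape[1]
    risks = np.array([_risk(Z[:, j], y, task) if usable[j] else np.inf
                      for j in range(L)])
    best = int(np.argmin(risks))
    w0 = np.zeros(L)
    w0[best] = 1.0
    free = np.where(usable)[0]
    if free.size == 1:
        return w0

    def obj(wf):
        w = np.zeros(L)
        w[free] = wf
        return _risk(Z @ w, y, task)

    cons = [{"type": "eq", "fun": lambda wf: np.sum(wf) - 1.0}]
    res = minimize(obj, w0[free], method="SLSQP",
                   bounds=[(0.0, 1.0)] * free.size, constraints=cons,
                   options={"maxiter": 300, "ftol": 1e-12})
    w = np.zeros(L)
    w[free] = np.clip(res.x, 0.0, None)
    s = w.sum()
    w = w / s if s > 0 else w0
    if _risk(Z @ w, y, task) > risks[best]:   # optimizer safeguard
        return w0
    return w


def cv_stack(X: np.ndarray, y: np.ndarray, library: list[LearnerSpec],
             task: str, folds: int = 10, seed: int = 0,
             columns: list[str] | None = None) -> EnsembleModel:
    """Fit the cross-validated convex stack.

    Out-of-fold base predictions are assembled per learner; simplex
    weights minimize the blended out-of-fold risk; base learners are then
    refit on the full data.  Binary tasks use stratified folds so no fold
    sees a single class.  Learners producing non-finite predictions get
    weight 0 with a warning.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute first)")
    if task == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary task requires y in {0, 1}")
    ids = {s.learner_id for s in library}
    if len(ids) != len(library):
        raise ValueError("learner_id values must be unique within a library")
    n, L = len(y), len(library)
    notes: list[str] = []

    if L == 1:
        learner = _FittedLearner(library[0], task, seed, columns).fit(X, y)
        pred = learner.predict(X)
        r = _risk(pred, y, task)
        return EnsembleModel(list(library), task, columns,
                             np.zeros(n, dtype=int), np.array([r]),
                             np.array([1.0]), [learner], r, seed,
                             ["single-learner library: cross-validation skipped"])

    if task == "binary":
        n_minor = int(min(np.bincount(y.astype(int))))
        if n_minor < 2:
            # too few minority outcomes to cross-validate: fit on full
            # data and weight the learner with the best in-sample risk
            learners = [_FittedLearner(s, task, seed, columns).fit(X, y)
                        for s in library]
            preds = np.column_stack([np.clip(l.predict(X), _CLIP, 1 - _CLIP)
                                     for l in learners])
            risks = np.array([_risk(preds[:, j], y, task) for j in range(L)])
            w = np.zeros(L)
            w[int(np.argmin(risks))] = 1.0
            return EnsembleModel(list(library), task, columns,
                                 np.zeros(n, dtype=int), risks, w, learners,
                                 float(risks.min()), seed,
                                 ["minority class < 2: CV skipped"])
        splitter = StratifiedKFold(min(folds, n_minor),
                                   shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = KFold(min(folds, n), shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    fold_of = np.empty(n, dtype=int)
    Z = np.full((n, L), np.nan)
    for f, (tr, te) in enumerate(split_iter):
        fold_of[te] = f
        for j, spec in enumerate(library):
            try:
                lj = _FittedLearner(spec, task, seed, columns).fit(X[tr], y[tr])
                Z[te, j] = lj.predict(X[te])
            except Exception as exc:  # pragma: no cover - defensive
                notes.append(f"{spec.learner_id} failed in fold {f}: {exc}")
                Z[te, j] = np.nan
    if task == "binary":
        Z = np.where(np.isnan(Z), Z, np.clip(Z, _CLIP, 1.0 - _CLIP))

    usable = np.all(np.isfinite(Z), axis=0)
    for j in np.where(~usable)[0]:
        warnings.warn(f"learner {library[j].learner_id!r} produced non-finite "
                      "out-of-fold predictions; weight forced to 0")
        notes.append(f"{library[j].learner_id}: weight forced to 0 (non-finite)")
        Z[:, j] = np.nanmean(y)
    if not usable.any():
        raise RuntimeError("no usable learners in library")

    cv_risks = np.array([_risk(Z[:, j], y, task) for j in range(L)])
    weights = _simplex_weights(Z, y, task, usable)
    ens_risk = _risk(Z @ weights, y, task)

    learners = [_FittedLearner(s, task, seed, columns).fit(X, y) for s in library]
    return EnsembleModel(list(library), task, columns, fold_of, cv_risks,
                         weights, learners, ens_risk, seed, notes)


def predict_ensemble(model: EnsembleModel, X_new: np.ndarray,
                     columns: list[str] | None = None) -> np.ndarray:
    """Weighted base-learner prediction; binary outputs clipped away
    from {0, 1}."""
    if columns is not None and model.columns is not None \
            and list(columns) != list(model.columns):
        extra = set(columns) - set(model.columns)
        missing = set(model.columns) - set(columns)
        raise ValueError(f"column mismatch: missing={sorted(missing)}, "
                         f"unexpected={sorted(extra)}")
    X_new = np.asarray(X_new, dtype=float)
    if model.columns is not None and X_new.shape[1] != len(model.columns):
        raise ValueError(f"X_new has {X_new.shape[1]} columns, "
                         f"model expects {len(model.columns)}")
    pred = np.zeros(X_new.shape[0])
    for w, learner in zip(model.weights, model.learners):
        if w > 0:
            pred += w * learner.predict(X_new)
    if model.task == "binary":
        pred = np.clip(pred, _CLIP, 1.0 - _CLIP)
    return pred
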