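"""Bayesian sum-of-trees (BART-style) backfitting sampler.

A compact implementation of the standard construction: m regression trees
with a depth-penalizing split prior alpha*(1+d)^-beta, conjugate normal
leaf values, Metropolis-Hastings grow/prune proposals on one tree at a
time against the partial residual, an inverse-chi-squared noise variance,
and (for binary outcomes) probit data augmentation.  Split-variable counts
over the retained posterior draws double as the importance tally.

Defaults are sized for use inside a cross-validated stacking library, not
for standalone inference.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["BartRegressor", "BartClassifier"]


class _Node:
    __slots__ = ("var", "thr", "left", "right", "mu", "depth")

    def __init__(self, depth: int):
        self.var = None
        self.thr = 0.0
        self.left = None
        self.right = None
        self.mu = 0.0
        self.depth = depth

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def copy(self) -> "_Node":
        n = _Node(self.depth)
        n.var, n.thr, n.mu = self.var, self.thr, self.mu
        if not self.is_leaf:
            n.left, n.right = self.left.copy(), self.right.copy()
        return n


def _leaves(node: _Node, out: list) -> list:
    if node.is_leaf:
        out.append(node)
    else:
        _leaves(node.left, out)
        _leaves(node.right, out)
    return out


def _parents_of_leaf_pairs(node: _Node, out: list) -> list:
    if not node.is_leaf:
        if node.left.is_leaf and node.right.is_leaf:
            out.append(node)
        _parents_of_leaf_pairs(node.left, out)
        _parents_of_leaf_pairs(node.right, out)
    return out


def _assign(node: _Node, X: np.ndarray, idx: np.ndarray,
            out: list[tuple[_Node, np.ndarray]]) -> None:
    if node.is_leaf:
        out.append((node, idx))
        return
    go_left = X[idx, node.var] <= node.thr
    _assign(node.left, X, idx[go_left], out)
    _assign(node.right, X, idx[~go_left], out)


def _predict_tree(node: _Node, X: np.ndarray) -> np.ndarray:
    pred = np.empty(X.shape[0])
    pairs: list[tuple[_Node, np.ndarray]] = []
    _assign(node, X, np.arange(X.shape[0]), pairs)
    for leaf, idx in pairs:
        pred[idx] = leaf.mu
    return pred


def _count_splits(node: _Node, counts: np.ndarray) -> None:
    if not node.is_leaf:
        counts[node.var] += 1
        _count_splits(node.left, counts)
        _count_splits(node.right, counts)


class _Sampler:
    """Shared backfitting machinery on a centered, scaled response."""

    def __init__(self, n_trees, n_burn, n_draw, alpha, beta, k, seed):
        self.m = n_trees
        self.n_burn = n_burn
        self.n_draw = n_draw
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.rng = np.random.Generator(np.random.Philox(key=[seed, 17]))
        self.forests_: list[list[_Node]] = []
        self.split_counts_: np.ndarray | None = None

    # --- priors ---
    def _p_split(self, depth: int) -> float:
        return self.alpha * (1.0 + depth) ** (-self.beta)

    def _leaf_loglik(self, sr: float, s2r: float, nn: int,
                     sigma2: float) -> float:
        # mu integrated out under N(0, tau2): marginal likelihood of leaf data
        tau2 = self.tau2
        v = sigma2 + nn * tau2
        return (0.5 * np.log(sigma2 / v)
                - s2r / (2.0 * sigma2)
                + tau2 * sr * sr / (2.0 * sigma2 * v))

    def _run(self, X: np.ndarray, z: np.ndarray, binary: bool) -> None:
        n, d = X.shape
        rng = self.rng
        self.tau2 = (0.5 / (self.k * np.sqrt(self.m))) ** 2
        trees = [_Node(0) for _ in range(self.m)]
        tree_pred = np.zeros((self.m, n))
        total = tree_pred.sum(axis=0)

        if binary:
            sigma2 = 1.0
        else:
            # nu/lambda prior calibrated so P(sigma < sd(z)) = 0.9
            from scipy.stats import chi2 as chi2_dist
            self._nu = 3.0
            shat2 = max(float(np.var(z)), 1e-12)
            self._lam = shat2 * chi2_dist.ppf(0.1, self._nu) / self._nu
            sigma2 = shat2

        counts_accum = np.zeros(d)
        y01 = z > 0  # only used in binary mode
        latent = z.copy()

        for it in range(self.n_burn + self.n_draw):
            if binary:
                # probit augmentation: truncated normal latent draw
                u = rng.random(n)
                lo = np.where(y01, norm.cdf(-total), 0.0)
                hi = np.where(y01, 1.0, norm.cdf(-total))
                q = np.clip(lo + u * (hi - lo), 1e-10, 1 - 1e-10)
                latent = total + norm.ppf(q)
            for t in range(self.m):
                total -= tree_pred[t]
                resid = latent - total
                self._update_tree(trees[t], X, resid, sigma2, rng)
                self._draw_leaf_values(trees[t], X, resid, sigma2, rng)
                tree_pred[t] = _predict_tree(trees[t], X)
                total += tree_pred[t]
            if not binary:
                sse = float(np.sum((latent - total) ** 2))
                df = self._nu + n
                sigma2 = (self._nu * self._lam + sse) / rng.chisquare(df)
            if it >= self.n_burn:
                self.forests_.append([tr.copy() for tr in trees])
                for tr in trees:
                    _count_splits(tr, counts_accum)
        self.split_counts_ = counts_accum

    def _update_tree(self, tree: _Node, X, resid, sigma2, rng) -> None:
        leaves = _leaves(tree, [])
        grow = tree.is_leaf or rng.random() < 0.5
        pairs: list[tuple[_Node, np.ndarray]] = []
        _assign(tree, X, np.arange(X.shape[0]), pairs)
        idx_of = {id(leaf): idx for leaf, idx in pairs}
        if grow:
            leaf = leaves[rng.integers(len(leaves))]
            idx = idx_of[id(leaf)]
            if idx.size < 2:
                return
            var = int(rng.integers(X.shape[1]))
            vals = np.unique(X[idx, var])
            if vals.size < 2:
                return
            thr = float(vals[rng.integers(vals.size - 1)])
            go_left = X[idx, var] <= thr
            li, ri = idx[go_left], idx[~go_left]
            if li.size == 0 or ri.size == 0:
                return
            r = resid[idx]
            rl, rr = resid[li], resid[ri]
            ll_new = (self._leaf_loglik(rl.sum(), (rl ** 2).sum(), li.size, sigma2)
                      + self._leaf_loglik(rr.sum(), (rr ** 2).sum(), ri.size, sigma2))
            ll_old = self._leaf_loglik(r.sum(), (r ** 2).sum(), idx.size, sigma2)
            ps = self._p_split(leaf.depth)
            psl = self._p_split(leaf.depth + 1)
            log_prior = (np.log(ps) + 2.0 * np.log(1.0 - psl) - np.log(1.0 - ps))
            # apply provisionally to count prunable pairs in the grown tree
            # (reverse prune picks this node among them); revert on reject
            leaf.var, leaf.thr = var, thr
            leaf.left = _Node(leaf.depth + 1)
            leaf.right = _Node(leaf.depth + 1)
            n_prunable_new = max(len(_parents_of_leaf_pairs(tree, [])), 1)
            # the tree prior's uniform split-rule probability (1/vars x
            # 1/cutpoints) cancels the matching proposal terms, leaving
            # only the leaf-count / prunable-count ratio
            log_prop = np.log(len(leaves)) - np.log(n_prunable_new)
            if not np.log(rng.random() + 1e-300) < (
                    ll_new - ll_old + log_prior + log_prop):
                leaf.var = None
                leaf.left = leaf.right = None
        else:
            prunable = _parents_of_leaf_pairs(tree, [])
            if not prunable:
                return
            node = prunable[rng.integers(len(prunable))]
            li = idx_of[id(node.left)]
            ri = idx_of[id(node.right)]
            idx = np.concatenate([li, ri])
            r, rl, rr = resid[idx], resid[li], resid[ri]
            ll_merged = self._leaf_loglik(r.sum(), (r ** 2).sum(), idx.size, sigma2)
            ll_split = (self._leaf_loglik(rl.sum(), (rl ** 2).sum(), li.size, sigma2)
                        + self._leaf_loglik(rr.sum(), (rr ** 2).sum(), ri.size, sigma2))
            ps = self._p_split(node.depth)
            psl = self._p_split(node.depth + 1)
            log_prior = -(np.log(ps) + 2.0 * np.log(1.0 - psl) - np.log(1.0 - ps))
            log_prop = np.log(len(prunable)) - np.log(len(leaves) - 1)
            if np.log(rng.random() + 1e-300) < ll_merged - ll_split + log_prior + log_prop:
                node.var = None
                node.left = node.right = None

    def _draw_leaf_values(self, tree: _Node, X, resid, sigma2, rng) -> None:
        pairs: list[tuple[_Node, np.ndarray]] = []
        _assign(tree, X, np.arange(X.shape[0]), pairs)
        tau2 = self.tau2
        for leaf, idx in pairs:
            nn = idx.size
            if nn == 0:
                leaf.mu = rng.normal(0.0, np.sqrt(tau2))
                continue
            v = 1.0 / (nn / sigma2 + 1.0 / tau2)
            mean = v * resid[idx].sum() / sigma2
            leaf.mu = rng.normal(mean, np.sqrt(v))

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for forest in self.forests_:
            for tree in forest:
                acc += _predict_tree(tree, X)
        return acc / len(self.forests_)


class BartRegressor:
    """Sum-of-trees regressor; response internally scaled to [-0.5, 0.5]."""

    def __init__(self, n_trees: int = 50, n_burn: int = 100, n_draw: int = 100,
                 alpha: float = 0.95, beta: float = 2.0, k: float = 2.0,
                 seed: int = 0):
        self.params = dict(n_trees=n_trees, n_burn=n_burn, n_draw=n_draw,
                           alpha=alpha, beta=beta, k=k, seed=seed)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._ymin, self._ymax = float(y.min()), float(y.max())
        rng_span = max(self._ymax - self._ymin, 1e-12)
        z = (y - self._ymin) / rng_span - 0.5
        self._span = rng_span
        self._sampler = _Sampler(**self.params)
        self._sampler._run(X, z, binary=False)
        return self

    def predict(self, X):
        z = self._sampler._raw_predict(X)
        return (z + 0.5) * self._span + self._ymin

    @property
    def split_counts_(self) -> np.ndarray:
        return self._sampler.split_counts_


class BartClassifier:
    """Probit sum-of-trees classifier via latent-normal augmentation."""

    def __init__(self, n_trees: int = 50, n_burn: int = 100, n_draw: int = 100,
                 alpha: float = 0.95, beta: float = 2.0, k: float = 2.0,
                 seed: int = 0):
        self.params = dict(n_trees=n_trees, n_burn=n_burn, n_draw=n_draw,
                           alpha=alpha, beta=beta, k=k, seed=seed)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        # encode classes in the latent sign; offset handled by the trees
        z = np.where(y > 0.5, 1.0, -1.0)
        self._sampler = _Sampler(**self.params)
        self._sampler._run(X, z, binary=True)
        return self

    def predict_proba(self, X):
        p1 = norm.cdf(self._sampler._raw_predict(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(float)

    @property
    def split_counts_(self) -> np.ndarray:
        return self._sampler.split_counts_
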