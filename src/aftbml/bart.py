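"""Bayesian additive regression trees for continuous outcomes.

The model is a sum of ``r`` binary regression trees,

    y_i = f(x_i) + eps_i,    f(x) = sum_j g(x; T_j, M_j),    eps_i ~ N(0, sigma^2),

with the regularizing tree prior of classical BART: a node at depth d is
nonterminal with probability ``alpha * (1 + d)^(-gamma)``, the split
covariate is uniform over the predictors, the split threshold is uniform
over the covariate values observed at the node, and terminal-node means are
``mu_jl ~ N(0, tau^2 / r)`` so that ``f(x) ~ N(0, tau^2)`` a priori.  The
error variance carries a scaled-inverse-chi-square prior
``sigma^2 ~ nu * lambda * inv-chi2(nu)``.

Sampling is by backfitting MCMC: per tree, a Metropolis-Hastings move
(grow / prune / change) on the structure with leaf means integrated out,
then conjugate normal draws of the leaf means, then the conjugate variance
draw.  The hot loops are compiled in :mod:`aftbml._compiled`; this module
provides the user-facing configuration, tree/forest containers, and a
step-wise sampler used for diagnostics and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _compiled as _c
from ._compiled import INTERNAL, LEAF, MAX_DEPTH, N_NODES, UNUSED
from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    InvalidStructureError,
)

__all__ = [
    "BartConfig",
    "DecisionTree",
    "Forest",
    "BartSampler",
    "nonterminal_prior_prob",
    "predict",
    "leaf_marginal_loglik",
    "tree_marginal_loglik",
    "gibbs_sigma2",
    "calibrate_tau",
    "draw_tree_from_prior",
]


def nonterminal_prior_prob(depth: int, alpha: float, gamma: float) -> float:
    """Prior probability that a node at ``depth`` is nonterminal,
    ``alpha * (1 + depth)^(-gamma)``."""
    if depth < 0 or int(depth) != depth:
        raise InvalidParameterError(f"depth must be a nonnegative integer, got {depth}")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if gamma < 0.0:
        raise InvalidParameterError(f"gamma must be nonnegative, got {gamma}")
    return alpha * (1.0 + depth) ** (-gamma)


@dataclass(frozen=True)
class BartConfig:
    """Tuning parameters of the sampler.

    ``n_trees`` is the ensemble size r; ``alpha``/``gamma`` parameterize the
    depth prior; ``nu``/``q`` calibrate the variance prior (the q-th prior
    quantile of sigma is matched to a least-squares estimate); ``tau`` is
    the prior SD of f(x) (calibrated from the response range when None,
    spanning it with ``tau_k`` prior SDs each side); ``n_burn`` and
    ``n_draws`` are burn-in and retained draw counts.
    """

    n_trees: int = 200
    alpha: float = 0.95
    gamma: float = 2.0
    nu: float = 3.0
    q: float = 0.9
    tau: float | None = None
    tau_k: float = 2.0
    n_burn: int = 1000
    n_draws: int = 1000
    thin: int = 1
    move_probabilities: tuple[float, float, float] = (0.25, 0.25, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.gamma < 0.0:
            raise InvalidParameterError("gamma must be >= 0")
        if self.nu <= 0.0:
            raise InvalidParameterError("nu must be > 0")
        if not 0.0 < self.q < 1.0:
            raise InvalidParameterError("q must lie in (0, 1)")
        if self.n_draws < 1:
            raise InvalidParameterError("n_draws must be >= 1")
        if self.n_burn < 0:
            raise InvalidParameterError("n_burn must be >= 0")
        if self.thin < 1:
            raise InvalidParameterError("thin must be >= 1")
        if self.tau is not None and self.tau <= 0.0:
            raise InvalidParameterError("tau must be positive")
        probs = self.move_probabilities
        if len(probs) != 3 or any(p < 0.0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
            raise InvalidParameterError(
                "move_probabilities must be three nonnegative weights summing to 1"
            )

    def with_(self, **kwargs) -> "BartConfig":
        return replace(self, **kwargs)


def calibrate_tau(y: np.ndarray, k: float = 2.0) -> float:
    """Prior SD of f(x) such that f spans the response range within k SDs."""
    rng = float(np.max(y) - np.min(y))
    return max(rng / (2.0 * k), 1e-10)


def gibbs_sigma2(sse: float, n: int, nu: float, lam: float,
                 rng: np.random.Generator) -> float:
    """One draw from the sigma^2 full conditional,
    (nu*lambda + SSE) / chi2(nu + n)."""
    return (nu * lam + sse) / rng.chisquare(nu + n)


class DecisionTree:
    """A single binary regression tree over a fixed-size node heap.

    Internal nodes hold a split rule (covariate index, threshold; ties
    ``x <= threshold`` route left); terminal nodes hold a leaf mean on the
    centered response scale.
    """

    def __init__(self, ntype: np.ndarray, var: np.ndarray,
                 cut: np.ndarray, leaf: np.ndarray) -> None:
        self.ntype = np.asarray(ntype, np.int8)
        self.var = np.asarray(var, np.int32)
        self.cut = np.asarray(cut, float)
        self.leaf = np.asarray(leaf, float)
        if self.ntype.shape != (N_NODES,):
            raise InvalidStructureError(f"expected {N_NODES} heap nodes")
        self._validate()

    def _validate(self) -> None:
        if self.ntype[0] == UNUSED:
            raise InvalidStructureError("root node is unused")
        for k in range(N_NODES):
            if self.ntype[k] == INTERNAL:
                kl, kr = 2 * k + 1, 2 * k + 2
                if kl >= N_NODES or self.ntype[kl] == UNUSED or self.ntype[kr] == UNUSED:
                    raise InvalidStructureError(f"internal node {k} lacks two children")

    @classmethod
    def stub(cls, value: float) -> "DecisionTree":
        """Single-leaf tree with constant prediction ``value``."""
        ntype = np.zeros(N_NODES, np.int8)
        ntype[0] = LEAF
        leaf = np.zeros(N_NODES)
        leaf[0] = value
        return cls(ntype, np.full(N_NODES, -1, np.int32), np.zeros(N_NODES), leaf)

    @classmethod
    def from_split(cls, var: int, cut: float, left_value: float,
                   right_value: float) -> "DecisionTree":
        """Depth-1 tree splitting on one covariate."""
        ntype = np.zeros(N_NODES, np.int8)
        ntype[0] = INTERNAL
        ntype[1] = LEAF
        ntype[2] = LEAF
        vars_ = np.full(N_NODES, -1, np.int32)
        vars_[0] = var
        cuts = np.zeros(N_NODES)
        cuts[0] = cut
        leaf = np.zeros(N_NODES)
        leaf[1] = left_value
        leaf[2] = right_value
        return cls(ntype, vars_, cuts, leaf)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.ntype == LEAF))

    @property
    def n_internal(self) -> int:
        return int(np.sum(self.ntype == INTERNAL))

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Heap index of the leaf each row of X falls into."""
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty(X.shape[0], np.int64)
        for i in range(X.shape[0]):
            k = 0
            while self.ntype[k] == INTERNAL:
                k = 2 * k + 1 if X[i, self.var[k]] <= self.cut[k] else 2 * k + 2
            out[i] = k
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf[self.assign(X)]


class Forest:
    """An ordered ensemble of trees; prediction is the sum over trees."""

    def __init__(self, trees: Sequence[DecisionTree], n_features: int | None = None) -> None:
        self.trees = list(trees)
        self.n_features = n_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.n_features is not None and X.shape[1] != self.n_features:
            raise InvalidInputError(
                f"expected {self.n_features} covariates, got {X.shape[1]}"
            )
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += tree.predict(X)
        return out

    def __len__(self) -> int:
        return len(self.trees)


def predict(forest: Forest, x: np.ndarray) -> np.ndarray | float:
    """Forest prediction at covariate vector(s) x (centered response scale)."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    out = forest.predict(np.atleast_2d(x))
    return float(out[0]) if single else out


def leaf_marginal_loglik(residuals: np.ndarray, sigma2: float, tau2_over_r: float) -> float:
    """Log marginal likelihood of one leaf's residuals with the
    N(0, tau^2/r) leaf mean integrated out."""
    resid = np.asarray(residuals, float)
    k = resid.size
    s = float(resid.sum())
    ss = float(resid @ resid)
    denom = sigma2 + k * tau2_over_r
    return (-0.5 * k * np.log(2.0 * np.pi * sigma2)
            + 0.5 * np.log(sigma2 / denom)
            - ss / (2.0 * sigma2)
            + tau2_over_r * s * s / (2.0 * sigma2 * denom))


def tree_marginal_loglik(tree: DecisionTree, X: np.ndarray,
                         partial_residuals: np.ndarray, sigma2: float,
                         tau2_over_r: float) -> float:
    """Log marginal likelihood of the partial residuals given the tree
    structure: the product over leaves of the normal-normal convolution."""
    if sigma2 <= 0.0:
        raise InvalidParameterError("sigma2 must be positive")
    resid = np.asarray(partial_residuals, float)
    assign = tree.assign(X)
    total = 0.0
    for k in np.flatnonzero(tree.ntype == LEAF):
        mask = assign == k
        if not mask.any():
            raise InvalidStructureError(f"leaf {k} receives no observations")
        total += leaf_marginal_loglik(resid[mask], sigma2, tau2_over_r)
    return total


def draw_tree_from_prior(X: np.ndarray, config: BartConfig,
                         rng: np.random.Generator,
                         tau2_over_r: float | None = None) -> DecisionTree:
    """Sample one tree (structure, rules and leaf means) from the prior.

    Used by prior-predictive diagnostics; mirrors the sampler's rule
    distribution (uniform covariate, threshold uniform over the values
    observed at the node, empty children disallowed, depth capped).
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if tau2_over_r is None:
        tau = config.tau if config.tau is not None else 1.0
        tau2_over_r = tau ** 2 / config.n_trees
    ntype = np.zeros(N_NODES, np.int8)
    var = np.full(N_NODES, -1, np.int32)
    cut = np.zeros(N_NODES)
    leaf = np.zeros(N_NODES)

    def build(k: int, rows: np.ndarray, depth: int) -> None:
        splittable = rows.size >= 2 and depth < MAX_DEPTH
        if splittable and rng.random() < nonterminal_prior_prob(depth, config.alpha, config.gamma):
            v = int(rng.integers(p))
            vals = X[rows, v]
            # rule prior: uniform over observed values with a nonempty
            # right child (the sampler's effective rule distribution)
            valid = vals[vals < vals.max()]
            if valid.size == 0:
                ntype[k] = LEAF
                leaf[k] = rng.normal(0.0, np.sqrt(tau2_over_r))
                return
            thr = valid[rng.integers(valid.size)]
            ntype[k] = INTERNAL
            var[k] = v
            cut[k] = thr
            left = rows[vals <= thr]
            right = rows[vals > thr]
            build(2 * k + 1, left, depth + 1)
            build(2 * k + 2, right, depth + 1)
        else:
            ntype[k] = LEAF
            leaf[k] = rng.normal(0.0, np.sqrt(tau2_over_r))

    build(0, np.arange(n), 0)
    return DecisionTree(ntype, var, cut, leaf)


class BartSampler:
    """Step-wise backfitting sampler over a fixed design.

    Intended for diagnostics and unit-level validation; the production
    fitting path (:func:`aftbml.aft.fit_aft_bart`) runs the whole chain in
    compiled code with identical move logic.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, config: BartConfig,
                 sigma2: float | None = None, seed: int | None = None) -> None:
        self.X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, float)))
        self.y = np.asarray(y, float).copy()
        if self.y.shape[0] != self.X.shape[0]:
            raise InvalidInputError("X and y lengths disagree")
        if not np.all(np.isfinite(self.y)):
            raise InvalidInputError("y must be finite")
        self.config = config
        n = self.X.shape[0]
        r = config.n_trees
        self.ntype = np.zeros((r, N_NODES), np.int8)
        self.ntype[:, 0] = LEAF
        self.var = np.full((r, N_NODES), -1, np.int32)
        self.cut = np.zeros((r, N_NODES))
        self.leaf = np.zeros((r, N_NODES))
        self.leaf_of = np.zeros((r, n), np.int32)
        self.fit = np.zeros(n)
        tau = config.tau if config.tau is not None else calibrate_tau(self.y, config.tau_k)
        self.tau2_over_r = tau ** 2 / r
        self.sigma2 = float(sigma2) if sigma2 is not None else float(np.var(self.y) + 1e-12)
        self.nu = config.nu
        self.lam = self.sigma2  # placeholder scale; overridden by callers that calibrate
        self._seed_gen = np.random.default_rng(config.seed if seed is None else seed)

    @property
    def forest(self) -> Forest:
        trees = [
            DecisionTree(self.ntype[j].copy(), self.var[j].copy(),
                         self.cut[j].copy(), self.leaf[j].copy())
            for j in range(self.config.n_trees)
        ]
        return Forest(trees, n_features=self.X.shape[1])

    @property
    def sse(self) -> float:
        e = self.y - self.fit
        return float(e @ e)

    def sweep(self, update_sigma: bool = True) -> None:
        """One Gibbs sweep: per-tree MH structure move + conjugate leaf
        draws, optionally followed by the sigma^2 draw."""
        p_grow, p_prune, _ = self.config.move_probabilities
        _c.seed_rng(int(self._seed_gen.integers(2 ** 31)))
        _c.one_sweep(self.X, self.y, self.ntype, self.var, self.cut, self.leaf,
                     self.leaf_of, self.fit, self.sigma2, self.tau2_over_r,
                     self.config.alpha, self.config.gamma, p_grow, p_prune)
        if update_sigma:
            self.sigma2 = gibbs_sigma2(self.sse, self.y.size, self.nu,
                                       self.lam, self._seed_gen)

    def run(self, n_sweeps: int, update_sigma: bool = True) -> None:
        for _ in range(n_sweeps):
            self.sweep(update_sigma=update_sigma)
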