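"""Log-normal accelerated failure time regression with a BART mean.

The event time t follows

    log t_i = mu + f(x_i) + eps_i,   eps_i ~ N(0, sigma^2),

with f a sum-of-trees (see :mod:`aftbml.bart`) and
``sigma^2 ~ nu*lambda*inv-chi2(nu)``.  Right censoring is handled by data
augmentation: at each Gibbs iteration the unobserved log event times of
censored individuals are drawn from a normal truncated to lie above the
observed log censoring time, after which the standard continuous-outcome
sweeps apply.

The centering constant mu defaults to the mean observed log time, and the
variance-prior scale lambda is calibrated so that the q-th prior quantile
of sigma equals the residual SD of a least-squares regression of log s on
the covariates.  Both calibrations use all observed times, censored
included (they affect only prior centering, not correctness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _compiled as _c
from .bart import BartConfig, DecisionTree, Forest, calibrate_tau
from .exceptions import FittingError, InvalidInputError, InvalidParameterError

__all__ = [
    "SurvivalData",
    "AFTPosterior",
    "center_constant",
    "residual_sd",
    "calibrate_sigma_prior",
    "impute_censored",
    "fit_aft_bart",
    "fit_bart",
]


@dataclass
class SurvivalData:
    """Right-censored outcomes: observed time ``s = min(t, c)`` and event
    indicator ``delta = I(t < c)`` with a covariate matrix X."""

    X: np.ndarray
    s: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.atleast_2d(np.asarray(self.X, float)))
        self.s = np.asarray(self.s, float)
        self.delta = np.asarray(self.delta, int)
        n = self.X.shape[0]
        if self.s.shape != (n,) or self.delta.shape != (n,):
            raise InvalidInputError("X, s and delta lengths disagree")
        if np.any(self.s <= 0.0) or not np.all(np.isfinite(self.s)):
            raise InvalidInputError("observed times must be strictly positive and finite")
        if not np.isin(self.delta, (0, 1)).all():
            raise InvalidInputError("delta must be coded 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def center_constant(s: np.ndarray) -> float:
    """Centering constant mu: the mean of log observed times."""
    s = np.asarray(s, float)
    if np.any(s <= 0.0):
        raise InvalidInputError("times must be strictly positive")
    return float(np.mean(np.log(s)))


def residual_sd(X: np.ndarray, log_s: np.ndarray) -> float:
    """SD of residuals from least squares of log s on X (with intercept)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(log_s, float)
    design = np.column_stack([np.ones(X.shape[0]), X])
    if X.shape[0] <= design.shape[1]:
        return float(np.std(y)) or 1.0
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sd = float(np.sqrt(resid @ resid / max(X.shape[0] - design.shape[1], 1)))
    return max(sd, 1e-8)


def calibrate_sigma_prior(sigma_hat: float, nu: float, q: float) -> float:
    """Scale lambda such that P(sigma < sigma_hat) = q under
    sigma^2 ~ nu*lambda*inv-chi2(nu).

    Uses the closed-form identity lambda = sigma_hat^2 * chi2_{1-q}(nu)/nu,
    since sigma^2 < sigma_hat^2 iff chi2(nu) > nu*lambda/sigma_hat^2.
    """
    if sigma_hat <= 0.0:
        raise InvalidParameterError("sigma_hat must be positive")
    if not 0.0 < q < 1.0 or nu <= 0.0:
        raise InvalidParameterError("need nu > 0 and q in (0, 1)")
    lam = sigma_hat ** 2 * stats.chi2.ppf(1.0 - q, nu) / nu
    if not np.isfinite(lam) or lam <= 0.0:
        raise FittingError("variance-prior calibration failed")
    return float(lam)


def impute_censored(log_s: np.ndarray, delta: np.ndarray, f_values: np.ndarray,
                    mu: float, sigma2: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Complete log event times: observed entries pass through, censored
    entries are drawn from N(mu + f, sigma^2) truncated to (log s, inf)."""
    if sigma2 <= 0.0:
        raise InvalidParameterError("sigma2 must be positive")
    log_s = np.asarray(log_s, float)
    delta = np.asarray(delta, int)
    out = log_s.copy()
    cens = delta == 0
    if cens.any():
        loc = mu + np.asarray(f_values, float)[cens]
        sd = np.sqrt(sigma2)
        a = (log_s[cens] - loc) / sd
        draws = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng)
        out[cens] = np.maximum(draws, np.nextafter(log_s[cens], np.inf))
    return out


class AFTPosterior:
    """Retained posterior draws of (f, sigma^2) plus the centering mu.

    Forests are stored as compact heap arrays; ``predict_f`` evaluates all
    retained forests at new covariate rows in compiled code.
    """

    def __init__(self, mu: float, ntype: np.ndarray, var: np.ndarray,
                 cut: np.ndarray, leaf: np.ndarray, sigma2: np.ndarray,
                 config: BartConfig, n_features: int) -> None:
        self.mu = float(mu)
        self._ntype = ntype
        self._var = var
        self._cut = cut
        self._leaf = leaf
        self.sigma2 = np.asarray(sigma2, float)
        self.config = config
        self.n_features = n_features
        if self.sigma2.ndim != 1 or self.sigma2.size < 1:
            raise InvalidParameterError("need at least one retained draw")
        if np.any(self.sigma2 <= 0.0):
            raise InvalidParameterError("sigma2 draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.sigma2.size

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)

    def forest(self, m: int) -> Forest:
        trees = [
            DecisionTree(self._ntype[m, j].copy(), self._var[m, j].copy(),
                         self._cut[m, j].copy(), self._leaf[m, j].copy())
            for j in range(self._ntype.shape[1])
        ]
        return Forest(trees, n_features=self.n_features)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, float)))
        if X.shape[1] != self.n_features:
            raise InvalidInputError(
                f"expected {self.n_features} covariates, got {X.shape[1]}"
            )
        return X

    def predict_f(self, X: np.ndarray) -> np.ndarray:
        """(n_draws, n_rows) matrix of centered-scale f draws at X."""
        X = self._check_X(X)
        return _c.draws_predict(self._ntype, self._var, self._cut, self._leaf, X)

    def mean_log_time_draws(self, X: np.ndarray) -> np.ndarray:
        """Per-draw mu + f(x): the conditional mean log event time."""
        return self.mu + self.predict_f(X)

    def survival_prob(self, X: np.ndarray, t: float,
                      return_draws: bool = False) -> np.ndarray:
        """Posterior-mean survival probability at time t,
        M^-1 sum_m Phi((mu + f_m(x) - log t) / sigma_m)."""
        if t <= 0.0:
            raise InvalidInputError("t must be positive")
        loc = self.mean_log_time_draws(X)
        z = (loc - np.log(t)) / self.sigma[:, None]
        draws = stats.norm.cdf(z)
        return draws if return_draws else draws.mean(axis=0)

    def median_time(self, X: np.ndarray, return_draws: bool = False) -> np.ndarray:
        """Posterior-mean median event time, M^-1 sum_m exp(mu + f_m(x))."""
        draws = np.exp(self.mean_log_time_draws(X))
        return draws if return_draws else draws.mean(axis=0)


def _prepare_chain(data: SurvivalData, config: BartConfig):
    log_s = np.log(data.s)
    mu = center_constant(data.s)
    yc = log_s - mu
    tau = config.tau if config.tau is not None else calibrate_tau(yc, config.tau_k)
    tau2r = tau ** 2 / config.n_trees
    sigma_hat = residual_sd(data.X, log_s)
    lam = calibrate_sigma_prior(sigma_hat, config.nu, config.q)
    cens_idx = np.flatnonzero(data.delta == 0).astype(np.int64)
    lower = yc[cens_idx].copy()
    return yc, mu, tau2r, lam, sigma_hat, cens_idx, lower


def fit_aft_bart(data: SurvivalData, config: BartConfig,
                 seed: int | None = None) -> AFTPosterior:
    """Fit the AFT model by Gibbs sampling, interleaving truncated-normal
    imputation of censored log times with backfitting sweeps, and retain
    ``config.n_draws`` post-burn-in draws of (f, sigma^2)."""
    yc, mu, tau2r, lam, sigma_hat, cens_idx, lower = _prepare_chain(data, config)
    p_grow, p_prune, _ = config.move_probabilities
    chain_seed = int((config.seed if seed is None else seed) % (2 ** 31))
    out = _c.run_chain(
        data.X, yc, cens_idx, lower, chain_seed, config.n_trees,
        config.n_burn, config.n_draws, config.thin, config.alpha, config.gamma,
        tau2r, config.nu, lam, sigma_hat ** 2, p_grow, p_prune,
    )
    ntype, var, cut, leaf, sigma2 = out
    return AFTPosterior(mu, ntype, var, cut, leaf, sigma2, config,
                        n_features=data.X.shape[1])


def fit_bart(X: np.ndarray, y: np.ndarray, config: BartConfig,
             seed: int | None = None) -> AFTPosterior:
    """Uncensored sum-of-trees fit of a continuous response: the same chain
    as :func:`fit_aft_bart` with every observation an event."""
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, float)))
    y = np.asarray(y, float)
    if y.shape[0] != X.shape[0]:
        raise InvalidInputError("X and y lengths disagree")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("y must be finite")
    mu = float(np.mean(y))
    yc = y - mu
    tau = config.tau if config.tau is not None else calibrate_tau(yc, config.tau_k)
    tau2r = tau ** 2 / config.n_trees
    sigma_hat = residual_sd(X, y)
    lam = calibrate_sigma_prior(sigma_hat, config.nu, config.q)
    p_grow, p_prune, _ = config.move_probabilities
    chain_seed = int((config.seed if seed is None else seed) % (2 ** 31))
    cens_idx = np.empty(0, np.int64)
    lower = np.empty(0, float)
    ntype, var, cut, leaf, sigma2 = _c.run_chain(
        X, yc, cens_idx, lower, chain_seed, config.n_trees,
        config.n_burn, config.n_draws, config.thin, config.alpha, config.gamma,
        tau2r, config.nu, lam, sigma_hat ** 2, p_grow, p_prune,
    )
    return AFTPosterior(mu, ntype, var, cut, leaf, sigma2, config,
                        n_features=X.shape[1])
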