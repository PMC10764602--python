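"""Parametric AFT Q-learning for two-stage censored outcomes.

Backward induction with user-specified stage-wise Q-function designs: the
Stage-2 model regresses log t2 on its design over entrants by censored
maximum likelihood (log-normal errors by default, minimum-Gumbel /
Weibull optionally); each entrant's optimal Stage-2 action and predicted
optimal time then augment the Stage-1 outcome (t1 plus the predicted
optimal Stage-2 time, treated as an event); the Stage-1 model is fit the
same way, and stage-wise optimal actions are the argmax of the fitted
conditional mean log time over the binary action set.

Uncertainty is by nonparametric bootstrap over individuals: each resample
reruns the full two-stage procedure and per-individual treatment contrasts
are summarized by normal-approximation intervals from the bootstrap SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateDesignError, FittingError, InvalidInputError

__all__ = [
    "Design",
    "QModel",
    "QLearnFit",
    "fit_censored_lognormal",
    "qlearn_two_stage",
    "bootstrap_predictions",
]


@dataclass(frozen=True)
class Design:
    """Q-function design: product terms over data columns plus an action
    column.  A term is a column name or a ':'-joined product of column
    names; ``extra`` maps derived column names to constructors evaluated
    on the data frame (for transformed covariates)."""

    terms: tuple[str, ...]
    action: str
    extra: tuple[tuple[str, Callable[[pd.DataFrame], np.ndarray]], ...] = ()

    @property
    def column_names(self) -> list[str]:
        return ["Intercept", *self.terms]

    def _augmented(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.extra:
            return df
        out = df.copy()
        for name, fn in self.extra:
            out[name] = np.asarray(fn(df), float)
        return out

    def build(self, df: pd.DataFrame, action_value: float | None = None) -> np.ndarray:
        """Design matrix with leading intercept; ``action_value`` overrides
        the action column (for counterfactual evaluation)."""
        aug = self._augmented(df)
        n = len(aug)
        cols = [np.ones(n)]
        for term in self.terms:
            prod = np.ones(n)
            for part in term.split(":"):
                if part == self.action and action_value is not None:
                    prod = prod * action_value
                else:
                    prod = prod * aug[part].to_numpy(float)
            cols.append(prod)
        return np.column_stack(cols)


def _nll_and_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                  delta: np.ndarray, dist: str):
    beta = params[:-1]
    g = params[-1]
    sigma = np.exp(g)
    z = (y - X @ beta) / sigma
    ev = delta == 1
    cn = ~ev
    if dist == "lognormal":
        ll_ev = stats.norm.logpdf(z[ev]) - g
        ll_cn = stats.norm.logsf(z[cn])
        lam = np.exp(stats.norm.logpdf(z[cn]) - stats.norm.logsf(z[cn]))
        dz = np.empty_like(z)
        dz[ev] = -z[ev]          # d loglik / dz
        dz[cn] = -lam
        dg_extra = -np.sum(ev)   # from the -g Jacobian term
    elif dist == "weibull":
        ez = np.exp(np.minimum(z, 700.0))
        ll_ev = -g + z[ev] - ez[ev]
        ll_cn = -ez[cn]
        dz = np.empty_like(z)
        dz[ev] = 1.0 - ez[ev]
        dz[cn] = -ez[cn]
        dg_extra = -np.sum(ev)
    else:
        raise InvalidInputError(f"unknown error distribution {dist!r}")
    nll = -(np.sum(ll_ev) + np.sum(ll_cn))
    # dz/dbeta_k = -x_k / sigma ; dz/dg = -z
    gbeta = -(X.T @ (dz * (-1.0 / sigma)))
    gg = -(np.sum(dz * (-z)) + dg_extra)
    return nll, np.append(gbeta, gg)


def _numeric_hessian(fun, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    p = x0.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            hi = eps * max(1.0, abs(x0[i]))
            hj = eps * max(1.0, abs(x0[j]))
            xpp = x0.copy(); xpp[i] += hi; xpp[j] += hj
            xpm = x0.copy(); xpm[i] += hi; xpm[j] -= hj
            xmp = x0.copy(); xmp[i] -= hi; xmp[j] += hj
            xmm = x0.copy(); xmm[i] -= hi; xmm[j] -= hj
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * hi * hj)
    return H


@dataclass
class QModel:
    """Fitted stage model: coefficients on the log-time scale and the
    residual scale (SD for log-normal errors, Gumbel scale for Weibull)."""

    design: Design
    coef: np.ndarray
    scale: float
    dist: str = "lognormal"
    cov: np.ndarray | None = field(default=None, repr=False)
    loglik: float = np.nan

    @property
    def coef_named(self) -> pd.Series:
        return pd.Series(self.coef, index=self.design.column_names)

    @property
    def standard_errors(self) -> pd.Series | None:
        if self.cov is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov)[: self.coef.size]),
                         index=self.design.column_names)

    def predict_log_time(self, df: pd.DataFrame,
                         action_value: float | None = None) -> np.ndarray:
        return self.design.build(df, action_value) @ self.coef

    def optimal_action(self, df: pd.DataFrame) -> np.ndarray:
        """Argmax of the predicted mean log time; ties to action 0."""
        p0 = self.predict_log_time(df, action_value=0.0)
        p1 = self.predict_log_time(df, action_value=1.0)
        return (p1 > p0).astype(int)


def fit_censored_lognormal(design_matrix: np.ndarray, s: np.ndarray,
                           delta: np.ndarray, dist: str = "lognormal",
                           compute_cov: bool = True,
                           design: Design | None = None) -> QModel:
    """Censored maximum likelihood for the AFT regression of log s on the
    design: events contribute the error density of log s, censored points
    the upper-tail probability.

    Initialized at the least-squares solution; with no censoring the
    log-normal MLE coincides with OLS (scale = ML residual SD).
    """
    X = np.atleast_2d(np.asarray(design_matrix, float))
    s = np.asarray(s, float)
    delta = np.asarray(delta, int)
    n, p = X.shape
    if np.any(s <= 0):
        raise InvalidInputError("times must be positive")
    if n < p + 2:
        raise DegenerateDesignError(f"need at least {p + 2} observations, have {n}")
    if not delta.any():
        raise DegenerateDesignError("all observations censored: model not identifiable")
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError("design matrix is rank deficient")
    y = np.log(s)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = max(float(np.sqrt(resid @ resid / n)), 1e-6)
    x0 = np.append(beta0, np.log(sigma0))
    res = optimize.minimize(
        _nll_and_grad, x0, args=(X, y, delta, dist), jac=True,
        method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    if not np.all(np.isfinite(res.x)):
        raise FittingError("censored AFT fit diverged")
    coef = res.x[:-1]
    scale = float(np.exp(res.x[-1]))
    cov = None
    if compute_cov:
        H = _numeric_hessian(
            lambda xx: _nll_and_grad(xx, X, y, delta, dist)[0], res.x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return QModel(design=design, coef=coef, scale=scale, dist=dist,
                  cov=cov, loglik=-res.fun)


def _fit_design(df: pd.DataFrame, design: Design, s, delta, dist,
                compute_cov=False) -> QModel:
    return fit_censored_lognormal(design.build(df), s, delta, dist=dist,
                                  compute_cov=compute_cov, design=design)


@dataclass
class QLearnFit:
    """Two fitted stage models plus entrant-level augmentation details."""

    stage2: QModel
    stage1: QModel
    a2_opt_entrants: np.ndarray
    pred_opt_t2_entrants: np.ndarray

    def optimal_action(self, df: pd.DataFrame, stage: int) -> np.ndarray:
        model = self.stage2 if stage == 2 else self.stage1
        return model.optimal_action(df)

    def predicted_optimal_log_time(self, df: pd.DataFrame, stage: int) -> np.ndarray:
        model = self.stage2 if stage == 2 else self.stage1
        a = model.optimal_action(df)
        p0 = model.predict_log_time(df, 0.0)
        p1 = model.predict_log_time(df, 1.0)
        return np.where(a == 1, p1, p0)

    def treatment_contrast(self, df: pd.DataFrame, stage: int) -> np.ndarray:
        model = self.stage2 if stage == 2 else self.stage1
        return model.predict_log_time(df, 1.0) - model.predict_log_time(df, 0.0)


def qlearn_two_stage(frame: pd.DataFrame, stage2_design: Design,
                     stage1_design: Design, dist: str = "lognormal",
                     compute_cov: bool = False) -> QLearnFit:
    """Backward-induction Q-learning on a two-stage frame (columns as in
    :class:`aftbml.dtr.TwoStageData`).

    The Stage-1 outcome of every entrant is t1 plus the model-predicted
    optimal Stage-2 time exp(x'beta) (the log-normal median), carried as an
    event; non-entrants keep their observed (s1, delta1).
    """
    ent = frame[frame["eta"] == 1]
    if len(ent) == 0:
        raise DegenerateDesignError("no Stage-2 entrants")
    if ent["a2"].nunique() < 2:
        raise DegenerateDesignError("only one Stage-2 action observed")
    q2 = _fit_design(ent, stage2_design, ent["s2"].to_numpy(float),
                     ent["delta2"].to_numpy(int), dist, compute_cov)
    a2_opt = q2.optimal_action(ent)
    p0 = q2.predict_log_time(ent, 0.0)
    p1 = q2.predict_log_time(ent, 1.0)
    pred_opt_t2 = np.exp(np.where(a2_opt == 1, p1, p0))

    s_star = frame["s1"].to_numpy(float).copy()
    d_star = frame["delta1"].to_numpy(int).copy()
    idx = np.flatnonzero(frame["eta"].to_numpy(int) == 1)
    s_star[idx] = s_star[idx] + pred_opt_t2
    d_star[idx] = 1
    q1 = _fit_design(frame, stage1_design, s_star, d_star, dist, compute_cov)
    return QLearnFit(stage2=q2, stage1=q1, a2_opt_entrants=a2_opt,
                     pred_opt_t2_entrants=pred_opt_t2)


def bootstrap_predictions(frame: pd.DataFrame, stage2_design: Design,
                          stage1_design: Design, eval_df: pd.DataFrame,
                          n_boot: int, seed: int = 0,
                          dist: str = "lognormal") -> dict:
    """Nonparametric bootstrap of the two-stage fit.

    Resamples individuals with replacement, reruns the full backward
    induction per resample, and returns per-individual bootstrap draws of
    the stage-wise treatment contrasts (log-time scale) over ``eval_df``,
    with normal-approximation 95% intervals centered at the full-data
    estimate.  Degenerate resamples are skipped and counted.
    """
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    full = qlearn_two_stage(frame, stage2_design, stage1_design, dist=dist)
    point = {st: full.treatment_contrast(eval_df, st) for st in (1, 2)}
    draws = {1: [], 2: []}
    skipped = 0
    n = len(frame)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        bframe = frame.iloc[idx].reset_index(drop=True)
        try:
            bfit = qlearn_two_stage(bframe, stage2_design, stage1_design, dist=dist)
        except (DegenerateDesignError, FittingError):
            skipped += 1
            continue
        for st in (1, 2):
            draws[st].append(bfit.treatment_contrast(eval_df, st))
    out = {"point": point, "n_skipped": skipped}
    for st in (1, 2):
        mat = np.array(draws[st]) if draws[st] else np.empty((0, len(eval_df)))
        se = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.full(len(eval_df), np.nan)
        out[f"stage{st}_draws"] = mat
        out[f"stage{st}_se"] = se
        out[f"stage{st}_ci"] = np.stack([point[st] - 1.96 * se, point[st] + 1.96 * se])
    return out
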