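"""Backward-induction estimation of a two-stage treatment regime from
right-censored survival data, with AFT-BART models at both stages.

Observed data per individual: baseline covariates o1, Stage-1 action a1,
Stage-1 time s1 with event indicator delta1, a Stage-2 entry indicator eta,
and — for entrants — Stage-2 covariates o2, action a2, and time s2 with
indicator delta2.  Actions are coded 0/1.

Algorithm (backward induction with parallel Stage-1 refits):

1. Fit the Stage-2 AFT model of (s2, delta2) on (o2bar, a2), where o2bar
   stacks baseline covariates, a1, optionally the Stage-1 pay-off log t1,
   and Stage-2 covariates.  Retain M posterior draws (f2_m, sigma2_m) and,
   per draw and individual, the sampled optimal action
   a2_opt_m = argmax_a f2_m(o2bar, a).
2. Per draw, construct the Stage-2 pseudo event time under optimal
   treatment: the observed log t2 when the observed action matched the
   sampled optimum and the event occurred; a truncated-normal draw (above
   log s2) when it matched but was censored; an unconstrained normal draw
   from the draw's predictive distribution otherwise.
3. Assemble the m-th augmented Stage-1 dataset: entrants get
   s1* = t1 + t2_opt_m as events; non-entrants keep (s1, delta1).
4. Fit M independent Stage-1 AFT-BART chains, one per augmented dataset,
   each burned in from scratch, retaining a single draw (f1_m, sigma1_m)
   and the per-individual optimal action a1_opt_m = argmax_a f1_m(o1, a).

Point rules take the action with the highest posterior frequency of being
optimal; outcome summaries (mean log time, median time, survival at t,
treatment differences) average per-draw quantities evaluated at each draw's
own sampled optimal action, with credible intervals from empirical
quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .aft import AFTPosterior, SurvivalData, fit_aft_bart
from .bart import BartConfig
from .exceptions import DegenerateDesignError, InvalidInputError

__all__ = [
    "TwoStageRecord",
    "TwoStageData",
    "DTRFit",
    "fit_dtr",
    "fit_stage2",
    "optimal_action_draws",
    "pseudo_outcome_draws",
    "assemble_stage1",
    "estimate_optimal_actions",
]

ACTION_SET = (0, 1)


@dataclass
class TwoStageRecord:
    """One individual's observed two-stage trajectory."""

    o1: np.ndarray
    a1: int
    s1: float
    delta1: int
    eta: int
    o2: np.ndarray | None = None
    a2: int | None = None
    s2: float | None = None
    delta2: int | None = None


@dataclass
class TwoStageData:
    """Two-stage records in tabular form.

    ``frame`` holds one row per individual with the standard columns
    a1, s1, delta1, eta and (for entrants) a2, s2, delta2; baseline and
    Stage-2 covariates live in the named columns.  Stage-2 fields are NaN
    exactly when eta = 0.
    """

    frame: pd.DataFrame
    baseline_cols: list[str]
    stage2_cols: list[str]

    def __post_init__(self) -> None:
        need = set(self.baseline_cols) | {"a1", "s1", "delta1", "eta"}
        missing = need - set(self.frame.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        if (self.frame["eta"] == 1).any():
            need2 = set(self.stage2_cols) | {"a2", "s2", "delta2"}
            missing2 = need2 - set(self.frame.columns)
            if missing2:
                raise InvalidInputError(f"missing Stage-2 columns: {sorted(missing2)}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def entrants(self) -> pd.DataFrame:
        return self.frame[self.frame["eta"] == 1]

    def to_records(self) -> list[TwoStageRecord]:
        recs = []
        for _, row in self.frame.iterrows():
            eta = int(row["eta"])
            recs.append(TwoStageRecord(
                o1=row[self.baseline_cols].to_numpy(float),
                a1=int(row["a1"]), s1=float(row["s1"]), delta1=int(row["delta1"]),
                eta=eta,
                o2=row[self.stage2_cols].to_numpy(float) if eta else None,
                a2=int(row["a2"]) if eta else None,
                s2=float(row["s2"]) if eta else None,
                delta2=int(row["delta2"]) if eta else None,
            ))
        return recs


def _stage1_matrix(df: pd.DataFrame, baseline_cols: Sequence[str],
                   a1_value: float | None = None) -> np.ndarray:
    a1 = np.full(len(df), a1_value, float) if a1_value is not None \
        else df["a1"].to_numpy(float)
    return np.column_stack([df[list(baseline_cols)].to_numpy(float), a1])


def _stage2_matrix(df: pd.DataFrame, baseline_cols: Sequence[str],
                   stage2_cols: Sequence[str], include_stage1_payoff: bool,
                   a2_value: float | None = None,
                   t1_col: str = "s1") -> np.ndarray:
    cols = [df[list(baseline_cols)].to_numpy(float),
            df["a1"].to_numpy(float)[:, None]]
    if include_stage1_payoff:
        cols.append(np.log(df[t1_col].to_numpy(float))[:, None])
    cols.append(df[list(stage2_cols)].to_numpy(float))
    a2 = np.full(len(df), a2_value, float) if a2_value is not None \
        else df["a2"].to_numpy(float)
    cols.append(a2[:, None])
    return np.column_stack(cols)


def optimal_action_draws(pred0: np.ndarray, pred1: np.ndarray) -> np.ndarray:
    """Per-draw argmax over the binary action set; exact ties break to the
    lowest-coded action (0)."""
    return (pred1 > pred0).astype(np.int8)


def estimate_optimal_actions(action_draws: np.ndarray) -> np.ndarray:
    """Point rule: the action with the highest posterior frequency among
    the sampled optima; ties to the lowest-coded action."""
    draws = np.atleast_2d(np.asarray(action_draws))
    return (draws.mean(axis=0) > 0.5).astype(int)


def pseudo_outcome_draws(pred_opt: np.ndarray, a_opt: np.ndarray,
                         a_obs: np.ndarray, delta2: np.ndarray,
                         log_s2: np.ndarray, sigma2: np.ndarray,
                         mu2: float, rng: np.random.Generator) -> np.ndarray:
    """Sample the (M, n2) matrix of Stage-2 log event times under optimal
    treatment, applying the three-case rule per draw and entrant.

    ``pred_opt[m, i]`` is the centered prediction f2_m at the sampled
    optimal action, ``a_opt`` the sampled optimal actions, ``a_obs`` /
    ``delta2`` / ``log_s2`` the observed Stage-2 data, ``sigma2`` the
    per-draw error variances.
    """
    M, n2 = pred_opt.shape
    out = np.empty((M, n2))
    loc = mu2 + pred_opt
    for m in range(M):
        matched = a_obs == a_opt[m]
        case_obs = matched & (delta2 == 1)
        case_trunc = matched & (delta2 == 0)
        case_free = ~matched
        out[m, case_obs] = log_s2[case_obs]
        if case_trunc.any():
            sd = np.sqrt(sigma2[m])
            a = (log_s2[case_trunc] - loc[m, case_trunc]) / sd
            draws = stats.truncnorm.rvs(a, np.inf, loc=loc[m, case_trunc],
                                        scale=sd, random_state=rng)
            out[m, case_trunc] = np.maximum(
                draws, np.nextafter(log_s2[case_trunc], np.inf))
        if case_free.any():
            out[m, case_free] = rng.normal(loc[m, case_free], np.sqrt(sigma2[m]))
    return out


def assemble_stage1(frame: pd.DataFrame, entrant_index: np.ndarray,
                    pseudo_log_t2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Augmented Stage-1 outcome for one retained draw: entrants get
    s1* = t1 + t2_opt as events, non-entrants keep (s1, delta1)."""
    s_star = frame["s1"].to_numpy(float).copy()
    d_star = frame["delta1"].to_numpy(int).copy()
    s_star[entrant_index] = s_star[entrant_index] + np.exp(pseudo_log_t2)
    d_star[entrant_index] = 1
    return s_star, d_star


def fit_stage2(data: TwoStageData, config: BartConfig,
               include_stage1_payoff: bool = True,
               seed: int | None = None) -> AFTPosterior:
    """AFT-BART fit of the Stage-2 outcome on (o2bar, a2) over entrants."""
    ent = data.entrants
    if len(ent) == 0:
        raise DegenerateDesignError("no Stage-2 entrants")
    a2 = ent["a2"].to_numpy(int)
    if len(np.unique(a2)) < 2:
        raise DegenerateDesignError("only one Stage-2 action observed")
    X2 = _stage2_matrix(ent, data.baseline_cols, data.stage2_cols,
                        include_stage1_payoff)
    sd = SurvivalData(X=X2, s=ent["s2"].to_numpy(float),
                      delta=ent["delta2"].to_numpy(int))
    return fit_aft_bart(sd, config, seed=seed)


def _task_seed(master_seed: int, task_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(task_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _fit_one_stage1(X1: np.ndarray, s_star: np.ndarray, d_star: np.ndarray,
                    config: BartConfig, seed: int):
    data = SurvivalData(X=X1, s=s_star, delta=d_star)
    post = fit_aft_bart(data, config, seed=seed)
    return (post.mu, post._ntype[0], post._var[0], post._cut[0],
            post._leaf[0], float(post.sigma2[0]))


@dataclass
class DTRFit:
    """Posterior summary of the fitted two-stage regime."""

    data: TwoStageData
    stage2: AFTPosterior
    include_stage1_payoff: bool
    mu1: np.ndarray                  # (M,) per-chain Stage-1 centering
    sigma1_sq: np.ndarray            # (M,)
    _s1_ntype: np.ndarray = field(repr=False, default=None)
    _s1_var: np.ndarray = field(repr=False, default=None)
    _s1_cut: np.ndarray = field(repr=False, default=None)
    _s1_leaf: np.ndarray = field(repr=False, default=None)
    a2_opt_draws_train: np.ndarray = field(repr=False, default=None)  # (M, n2)
    a1_opt_draws_train: np.ndarray = field(repr=False, default=None)  # (M, n)
    pseudo_log_t2: np.ndarray = field(repr=False, default=None)       # (M, n2)

    @property
    def n_draws(self) -> int:
        return self.mu1.size

    # ---- per-draw predictions -------------------------------------------
    def stage2_action_values(self, df: pd.DataFrame, t1_col: str = "s1"):
        """(M, n) centered f2 draws at a2 = 0 and a2 = 1."""
        args = (self.data.baseline_cols, self.data.stage2_cols,
                self.include_stage1_payoff)
        X0 = _stage2_matrix(df, *args, a2_value=0.0, t1_col=t1_col)
        X1 = _stage2_matrix(df, *args, a2_value=1.0, t1_col=t1_col)
        return self.stage2.predict_f(X0), self.stage2.predict_f(X1)

    def _stage1_predict(self, X: np.ndarray) -> np.ndarray:
        from . import _compiled as _c
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, float)))
        return _c.draws_predict(self._s1_ntype, self._s1_var,
                                self._s1_cut, self._s1_leaf, X)

    def stage1_action_values(self, df: pd.DataFrame):
        """(M, n) centered f1 draws at a1 = 0 and a1 = 1."""
        X0 = _stage1_matrix(df, self.data.baseline_cols, a1_value=0.0)
        X1 = _stage1_matrix(df, self.data.baseline_cols, a1_value=1.0)
        return self._stage1_predict(X0), self._stage1_predict(X1)

    def _draws(self, df: pd.DataFrame, stage: int, t1_col: str = "s1"):
        """Per-draw (optimal action, mean log time at that action,
        sigma draw) triples for each row of df."""
        if stage == 2:
            p0, p1 = self.stage2_action_values(df, t1_col=t1_col)
            a_opt = optimal_action_draws(p0, p1)
            loc = self.stage2.mu + np.where(a_opt == 1, p1, p0)
            sig = self.stage2.sigma[:, None]
        elif stage == 1:
            p0, p1 = self.stage1_action_values(df)
            a_opt = optimal_action_draws(p0, p1)
            loc = self.mu1[:, None] + np.where(a_opt == 1, p1, p0)
            sig = np.sqrt(self.sigma1_sq)[:, None]
        else:
            raise InvalidInputError("stage must be 1 or 2")
        return a_opt, loc, sig

    # ---- summaries -------------------------------------------------------
    def optimal_actions(self, df: pd.DataFrame, stage: int,
                        t1_col: str = "s1") -> np.ndarray:
        a_opt, _, _ = self._draws(df, stage, t1_col=t1_col)
        return estimate_optimal_actions(a_opt)

    def posterior_mean_log_time(self, df: pd.DataFrame, stage: int,
                                level: float = 0.95,
                                t1_col: str = "s1") -> pd.DataFrame:
        """Posterior mean of the log event time under optimal treatment,
        each draw evaluated at its own sampled optimal action, with
        equal-tailed credible intervals from empirical quantiles."""
        _, loc, _ = self._draws(df, stage, t1_col=t1_col)
        lo, hi = np.quantile(loc, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
        return pd.DataFrame({"mean": loc.mean(axis=0), "lower": lo, "upper": hi},
                            index=df.index)

    def treatment_difference(self, df: pd.DataFrame, stage: int,
                             scale: str = "log-time", t: float | None = None,
                             t1_col: str = "s1") -> pd.DataFrame:
        """Posterior contrast of action 1 minus action 0 on the requested
        scale ('log-time', 'median' or 'survival-at-t'); positive values
        favor action 1.  Returns mean with 95% and 50% intervals."""
        if stage == 2:
            p0, p1 = self.stage2_action_values(df, t1_col=t1_col)
            mu = self.stage2.mu
            sig = self.stage2.sigma[:, None]
        else:
            p0, p1 = self.stage1_action_values(df)
            mu = self.mu1[:, None]
            sig = np.sqrt(self.sigma1_sq)[:, None]
        if scale == "log-time":
            diff = p1 - p0
        elif scale == "median":
            diff = np.exp(mu + p1) - np.exp(mu + p0)
        elif scale == "survival-at-t":
            if t is None or t <= 0:
                raise InvalidInputError("survival-at-t scale needs t > 0")
            lt = np.log(t)
            diff = stats.norm.cdf((mu + p1 - lt) / sig) \
                - stats.norm.cdf((mu + p0 - lt) / sig)
        else:
            raise InvalidInputError(f"unknown scale {scale!r}")
        q = np.quantile(diff, [0.025, 0.25, 0.75, 0.975], axis=0)
        return pd.DataFrame(
            {"mean": diff.mean(axis=0), "lo95": q[0], "lo50": q[1],
             "hi50": q[2], "hi95": q[3]}, index=df.index)


def fit_dtr(data: TwoStageData, config: BartConfig, n_workers: int = 1,
            include_stage1_payoff: bool = True,
            seed: int | None = None) -> DTRFit:
    """Run the full backward-induction algorithm and return the fitted
    regime.  Results are independent of ``n_workers`` (each Stage-1 chain
    and the pseudo-outcome stream use seeds derived from the master seed by
    task index)."""
    master_seed = int(config.seed if seed is None else seed)
    stage2 = fit_stage2(data, config, include_stage1_payoff,
                        seed=_task_seed(master_seed, 0))
    ent = data.entrants
    entrant_index = np.flatnonzero(data.frame["eta"].to_numpy(int) == 1)
    args = (data.baseline_cols, data.stage2_cols, include_stage1_payoff)
    X0 = _stage2_matrix(ent, *args, a2_value=0.0)
    X1 = _stage2_matrix(ent, *args, a2_value=1.0)
    p0 = stage2.predict_f(X0)
    p1 = stage2.predict_f(X1)
    a2_opt = optimal_action_draws(p0, p1)
    pred_opt = np.where(a2_opt == 1, p1, p0)

    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 1]))
    pseudo = pseudo_outcome_draws(
        pred_opt, a2_opt, ent["a2"].to_numpy(int), ent["delta2"].to_numpy(int),
        np.log(ent["s2"].to_numpy(float)), stage2.sigma2, stage2.mu, rng)

    X1mat = _stage1_matrix(data.frame, data.baseline_cols)
    cfg1 = config.with_(n_draws=1)
    M = config.n_draws
    tasks = []
    for m in range(M):
        s_star, d_star = assemble_stage1(data.frame, entrant_index, pseudo[m])
        tasks.append((s_star, d_star, _task_seed(master_seed, 2 + m)))
    if n_workers > 1:
        results = Parallel(n_jobs=n_workers, backend="loky")(
            delayed(_fit_one_stage1)(X1mat, s, d, cfg1, sd) for s, d, sd in tasks)
    else:
        results = [_fit_one_stage1(X1mat, s, d, cfg1, sd) for s, d, sd in tasks]

    mu1 = np.array([r[0] for r in results])
    s1_ntype = np.stack([r[1] for r in results])
    s1_var = np.stack([r[2] for r in results])
    s1_cut = np.stack([r[3] for r in results])
    s1_leaf = np.stack([r[4] for r in results])
    sigma1_sq = np.array([r[5] for r in results])

    fit = DTRFit(data=data, stage2=stage2,
                 include_stage1_payoff=include_stage1_payoff,
                 mu1=mu1, sigma1_sq=sigma1_sq,
                 _s1_ntype=s1_ntype, _s1_var=s1_var, _s1_cut=s1_cut,
                 _s1_leaf=s1_leaf, a2_opt_draws_train=a2_opt,
                 pseudo_log_t2=pseudo)
    f0, f1 = fit.stage1_action_values(data.frame)
    fit.a1_opt_draws_train = optimal_action_draws(f0, f1)
    return fit
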