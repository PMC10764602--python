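# aftbml

Estimation of **optimal two-stage dynamic treatment regimes (DTRs) from
right-censored survival data**, using Bayesian additive regression trees
(BART) under a log-normal accelerated failure time (AFT) model, with a
parametric AFT Q-learning comparator and a replicated simulation benchmark.

The intended users are biostatisticians analysing sequential-treatment
cohorts — the motivating setting is allogeneic hematopoietic cell
transplantation, where an initial graft-versus-host-disease prophylaxis
(Stage 1) may be followed by a salvage treatment (Stage 2) — and
methodologists who want a self-contained, testable reference implementation
of the backward-induction Gibbs approach for censored outcomes.

## The model

Each stage k has an AFT-BART regression of the stage event time on the
accumulated history and action,

    log t_k = mu_k + f_k(h_k, a_k) + eps_k,   eps_k ~ N(0, sigma_k^2),

where f_k is a sum of r regression trees with the standard regularizing
prior (a node at depth d is nonterminal with probability
alpha (1 + d)^(-gamma); terminal-node means are N(0, tau^2/r);
sigma_k^2 ~ nu lambda inv-chi2(nu)), and censored log times are imputed
from truncated normals inside the Gibbs loop.

The optimal regime is estimated by backward induction:

1. fit the Stage-2 model on entrants and retain M posterior draws;
2. per draw, sample each entrant's optimal Stage-2 action
   `a2_opt = argmax_a f2(h2, a)` and a Stage-2 event time under that
   action — the observed time when the observed action matched the
   sampled optimum and the event occurred, a truncated posterior
   predictive draw when it matched but was censored, and an unconstrained
   predictive draw otherwise;
3. build M augmented Stage-1 datasets with pseudo-outcomes
   `s1* = t1 + t2_opt` for entrants (as events);
4. fit M independent Stage-1 chains, one per augmented dataset, keeping
   one draw each.

Point rules take the action with the highest posterior frequency of being
optimal; outcome summaries (mean log event time, median time, survival
probability at t, treatment differences on any of these scales) average
per-draw quantities and report empirical-quantile credible intervals.
The comparator is classical Q-learning with user-specified parametric
Q-functions fit by censored maximum likelihood (log-normal or Weibull
errors), with nonparametric-bootstrap uncertainty.

## Worked example

```python
from aftbml import BartConfig, TwoStageData, fit_dtr, generate, ScenarioConfig
from aftbml.scenarios import BASELINE_COLS, STAGE2_COLS

ds = generate(ScenarioConfig(scenario=1, n=400, seed=11))   # linear scenario
data = TwoStageData(ds.data, BASELINE_COLS, STAGE2_COLS)
cfg = BartConfig(n_trees=50, n_burn=250, n_draws=100, thin=5, seed=1)
fit = fit_dtr(data, cfg, seed=1)

a1 = fit.optimal_actions(data.frame, 1)
print((a1 == ds.truth["a1_opt"]).mean())        # 0.87
print(fit.posterior_mean_log_time(data.frame.head(3), 1).round(3))
print(fit.treatment_difference(data.frame.head(3), 1).round(3))
```

prints (400 individuals, ~22% censoring, 239 Stage-2 entrants):

```
0.87
    mean  lower  upper
0  7.590  7.355  7.805
1  7.411  7.213  7.600
2  6.947  6.760  7.181
    mean   lo95   lo50   hi50   hi95
0  0.683  0.517  0.624  0.735  0.882
1  0.601  0.433  0.541  0.665  0.744
2 -0.010 -0.271 -0.083  0.071  0.199
```

The first table is the posterior mean log event time under optimal
treatment with a 95% credible interval, per individual.  The second is the
Stage-1 treatment contrast on the log-time scale (action 1 minus action
0) with 95% and 50% intervals: individuals 0 and 1 clearly benefit from
action 1 (intervals exclude zero), individual 2 is indifferent.  At this
sample size the estimated Stage-1 rule agrees with the generating rule
I(0.1 − 0.2·x1 + 0.6·b1 > 0) for 87% of individuals.

A command-line interface mirrors the library:

```bash
aftbml simulate --scenario 1 --n 800 --seed 7 --out scn1.csv
aftbml fit-dtr --data scn1.csv --out fit.csv --trees 50 --burn 250 --draws 100
aftbml benchmark --scenario 2 --methods aft-bml,q-oracle,q-lin --reps 20 --out bench.csv
aftbml summarize --data scn1.csv --contrasts fit.csv --out tree.txt
```

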