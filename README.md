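# nof1sim

Simulation and causal analysis of **aggregated N-of-1 trials** with
treatment carry-over.

N-of-1 trials are multi-crossover trials in which each patient alternates
between treatments and serves as their own control; aggregating a series of
them yields population-level treatment-effect estimates. Two features make
the aggregated analysis hard: **carry-over** (one treatment's effect is
still washing out while the other is given) and **covariate-dependent
treatment effects**. `nof1sim` provides

* a DAG-based daily-data simulator for a series of back-pain N-of-1 trials
  (linear structural equations with lags, exponential-decay carry-over, a
  Wiener-process baseline drift, ordinal 0–10 pain outcome, and two dropout
  mechanisms), and
* five estimators of the average treatment effect difference, organised as
  model objects whose `fit()` returns a results object:
  * `SampleMeanContrast` — naive difference of group means,
  * `TrialLinearModel` — covariate-adjusted pooled OLS,
  * `COAPM` — the **carry-over adjusted parametric model**: OLS on
    exponential-decay exposure regressors
    `E_k^t = E_k^{t-1} + (1-E_k^{t-1})/tau_k * T_k^t - E_k^{t-1}/gamma_k * (1-T_k^t)`
    with the wash-in/wash-out parameters `(tau_k, gamma_k)` selected by an
    R²-maximizing grid search,
  * `GEstimation` — structural-nested-mean-model G-estimation: the root of
    `theta_1(psi)` in the GEE-fitted propensity model
    `logit P(T=1 | H(psi), C) = theta_0 + theta_1 H(psi) + theta_2' C` with
    `H(psi) = O - psi T`, under independence or AR1 working correlation,
  * `BayesianNetworkATE` — linear-Gaussian Bayesian network on the assumed
    DAG (optionally lag-1 augmented), with the ATE estimated by intervention
    sampling (1000 forward samples per arm),

plus a Monte-Carlo harness (`run_scenario`, `full_study`) that compares bias
and efficiency across four scenarios (carry-over x activity interaction),
with and without missing data, for samples of 5–100 patients.

## Worked example

```python
import nof1sim as n1

graph = n1.load_backpain_graph()            # the packaged causal DAG
config = n1.scenario_config(2)              # carry-over: tau=(6,5), gamma=(3,4)
cohort = n1.simulate_cohort(graph, config, n_patients=25, seed=7)

print(n1.SampleMeanContrast(cohort).fit().summary())
print(n1.COAPM(cohort).fit().summary())
```

```
SampleMeanResults (method=sample_mean)
  effect difference (T1 - T2):  1.6179
  mean_t1: 4.140714285714286
  mean_t2: 2.5228571428571427
COAPMResults (method=coapm)
  effect difference (T1 - T2):  1.8930
  standard error:               0.0281
  beta1: -1.7195730915635978
  beta2: -3.6125439864641136
  tau1: 7.0
  gamma1: 3.0
  tau2: 5.0
  gamma2: 4.0
  r_squared: 0.7688191931717341
  aliased: False
```

The simulated truth is an effect difference of 2 (treatment effects −2 and
−4 on the pain scale versus no treatment). Under carry-over the naive
contrast is biased low (1.62) because early-period days carry the previous
treatment's residual effect, while the COAPM — which models the wash-in and
wash-out explicitly and selected `(tau1, gamma1, tau2, gamma2) = (7, 3, 5, 4)`
on this sample — is close to the truth; averaged over 100 samples of 25
patients it is unbiased (see below).

The same analyses are available from the shell:

```sh
nof1sim simulate --scenario 2 --n-patients 25 --seed 7 --out trial.csv
nof1sim analyze  --method coapm --in trial.csv --out coapm.json
nof1sim evaluate --scenarios 1,2 --sizes 5,25 --replicates 20 --seed 1 --out results/
```

## Layout

```
src/nof1sim/
  graph.py        declarative causal model (nodes, weighted/lagged edges)
  scenarios.py    the four study scenarios and the packaged back-pain DAG
  simulate.py     designs, exposure decay, baseline drift, cohorts, dropout
  estimators/     the five estimators (statsmodels-style Model -> Results)
  montecarlo.py   bias/efficiency evaluation harness
  plotting.py     summary figure (estimate +- empirical SE vs sample size)
  io.py, cli.py   CSV/JSON I/O, run manifests, click CLI
docs/methods.md   modelling assumptions, defaults, numerical choices
```
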