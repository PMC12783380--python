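# ipcwjack

Prediction uncertainty for binary classifiers applied to right-censored
survival data.

## The problem

Clinical prediction models often target the probability of surviving a fixed
horizon τ — e.g. annual patient or graft survival after transplantation.
Binary classifiers can be used for this by dichotomizing the event time into
Y = I(T\* ≥ τ), but censoring makes Y unobservable for subjects lost to
follow-up before both τ and their event. Inverse-probability-of-censoring
weighting (IPCW) handles this: those subjects get weight 0 and everyone else
is up-weighted by the inverse of the estimated censoring-survival function
Ĝ(u) = P̂(C > u) (a reverse Kaplan–Meier estimate),

    w̃ᵢ = 0                 if cᵢ < tᵢ* ∧ τ,
    w̃ᵢ = 1 / Ĝ(τ)          if tᵢ ≥ τ,
    w̃ᵢ = 1 / Ĝ(tᵢ)         if the event occurred before τ,

with normalized weights wᵢ = w̃ᵢ / Σₖ w̃ₖ. A classifier minimizing the
IPC-weighted binary log loss then yields asymptotically unbiased predictions
of p = P(T\* ≥ τ | X = x). What has been missing is a model-free standard
error for such predictions. This package implements an **IPCW-adjusted
infinitesimal jackknife**:

    Var̂(p̂) = Σᵢ (1 − wᵢ) (p̂ − p̂₋ᵢ)²,

where p̂₋ᵢ is the prediction refitted with record i removed and the
remaining weights renormalized by 1/(1 − wᵢ), holding Ĝ fixed. For the
IPC-weighted mean this reduces exactly to the unbiased sample variance
of the m non-zero-weight outcomes, and the single-jump Greenwood variance
d(m − d)/m³ is its (m − 1)/m multiple. Confidence intervals are formed on
the logit scale and back-transformed, so they always lie inside [0, 1].

The package ships the weighting machinery, three reference classifiers
(IPC-weighted mean, IPC-weighted logistic GLM with robust model-based SEs,
and a log-logistic AFT survival comparator), a plugin adapter for any
sklearn-style classifier honouring `sample_weight` (gradient boosting by
default), and an ADEMP simulation harness that measures bias, SE accuracy,
confidence-interval coverage and IPC-weighted Brier scores.

## Worked example

A six-subject toy dataset (`demo.csv`), horizon τ = 4, covariate-free
IPC-weighted mean:

```sh
$ ipcwjack analyze demo.csv --tau 4 --method weighted_mean
z,p_hat,se,ci_low,ci_high,se_method,n,n_zero_weight,pct_zero_weight
0,0.625,0.2727397,0.1455468,0.9422210,adjusted_jackknife,6,2,33.33
```

Two of the six subjects are censored before both τ and an event
(`n_zero_weight=2`); the reverse Kaplan–Meier weights make the four
remaining subjects carry normalized weights (1/6, 5/24, 5/16, 5/16), giving
p̂ = 5/8 = 0.625. The adjusted jackknife SE 0.2727 reflects the effective
sample of four informative subjects, and the logit-scale 95% CI
(0.146, 0.942) stays inside the unit interval.

On a simulated 400-subject dataset with ~25% zero weights, the IPC-weighted
logistic model at two covariate patterns:

```sh
$ ipcwjack analyze sim.csv --tau 5 --method ipcw_glm --query "1,1;1,0"
x1,x2,p_hat,se,ci_low,ci_high,se_method,n,n_zero_weight,pct_zero_weight
1,1,0.4338,0.0557,0.3294,0.5443,adjusted_jackknife,400,106,26.5
1,0,0.3073,0.0473,0.2231,0.4067,adjusted_jackknife,400,106,26.5
```

Each row is one covariate pattern: the predicted survival probability at
τ = 5, its adjusted-jackknife SE (one warm-started leave-one-out refit per
non-zero-weight subject) and the logit-scale CI.

The library mirrors the CLI: `compute_ipc_weights`, `fit_weighted_logit`,
`adjusted_jackknife_se`, `logit_ci`, `run_scenario`, … — see the module
docstrings and `docs/methods.md`.

`ipcwjack simulate scenario.json` runs one simulation scenario from a JSON
config; `ipcwjack reproduce-tables` runs the reduced simulation grid and
writes tidy CSV plus formatted text tables.

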