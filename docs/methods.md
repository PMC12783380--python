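# Methods

## Model and estimand

For subject i we observe (xᵢ, tᵢ, δᵢ): covariates, the follow-up time
T = T\* ∧ C (event time T\*, censoring time C, assumed conditionally
independent given X) and the event indicator δ = I(T\* ≤ C). The estimand is
the survival probability at a fixed horizon, p = P(T\* ≥ τ | X = x),
equivalently P(Y = 1 | X = x) for the dichotomized outcome Y = I(T\* ≥ τ).
A follow-up time of exactly τ counts as surviving (closed lower bound);
subjects censored before both τ and an event have unobservable Y and are
labelled UNKNOWN.

## IPC weighting

The censoring-survival function G(u) = P(C > u) is estimated marginally
(covariate-free) by the reverse Kaplan–Meier product-limit estimator,
treating censorings as events and events as censorings. At tied times,
events are ordered before censorings within the risk set, so a subject with
an event at u remains at risk for a censoring jump at u; this tie rule
reproduces the two-point tractable example exactly (Ĝ = m/n between the
censoring atom and the next jump). Ĝ is evaluated right-continuously,
matching P(C > u). Raw weights are 0 / 1/Ĝ(τ) / 1/Ĝ(tᵢ) for
UNKNOWN / survivor / early-event subjects; normalized weights divide by the
raw sum. A Ĝ of zero at a required evaluation point raises an error with
the offending time rather than silently truncating — with the internally
estimated marginal Ĝ this cannot occur (the subject needing Ĝ(u) is itself
in every earlier risk set), so the guard protects externally supplied
curves. Covariate-conditional censoring models are a documented limitation,
not implemented.

## Classifiers

All weighted classifiers minimize the IPC-weighted binary log loss; its
expectation is minimized by the true conditional survival probability,
which is what makes the predictions asymptotically unbiased.

* **Weighted mean** — Σ wₖyₖ, the analytically tractable case.
* **Weighted logistic GLM** — our own IRLS with step-halving; convergence at
  relative coefficient change < 1e-8, cap 100 iterations; warm starts
  accepted (the leave-one-out sweep starts each refit at the full-sample
  solution, cutting its cost roughly tenfold at unchanged tolerance). The
  linear predictor carries a fixed offset, −ln τ by default, so fitted
  intercepts are directly comparable to the generating-model coefficients;
  predictions are offset-invariant. The IRLS path is exactly invariant to
  rescaling the weight vector, so leave-one-out renormalization does not
  change coefficients and the fast sweep equals from-scratch refits.
  The coefficient covariance is the robust sandwich A⁻¹BA⁻¹ over the
  weighted score equations (A the raw-weight information, B the outer
  product of raw-weight scores). Because IPC weights vary across subjects,
  the weighted scores are over-dispersed relative to the information and
  the plain inverse information understates prediction variance by ~15–20%
  under 25% zero weights; the sandwich restores the correct scale while
  still treating Ĝ as fixed (no correction for its estimation — slightly
  conservative in practice, since estimating Ĝ reduces variance).
* **Log-logistic AFT** — the survival-analysis comparator fitted by
  censored maximum likelihood via lifelines' `LogLogisticAFTFitter`;
  S(τ|x) = (1 + (τ/exp(b′(1,x)))^a)⁻¹. Delta-method SEs use the joint
  covariance of (b, ln a).
* **Plugin** — any estimator with `fit(X, y, sample_weight)` and
  `predict_proba`; the default is xgboost (depth 2, 100 rounds, learning
  rate 0.1, exact tree method, single thread, fixed seed — package
  defaults, chosen for determinism and small-sample stability, not tuned).
  Raw weights are passed as sample weights, so doubling a record's raw
  weight is exactly equivalent to duplicating the record; a canary test
  enforces this contract.

Probability clipping (ε = 1e-10) applies to loss evaluation only; fitted
predictions are never clipped. Non-convergent fits raise a flagged error;
inside simulations the replicate is excluded for that method with a logged
count, and coverage denominators use converged replicates only.

## Adjusted jackknife

Var̂(p̂) = Σᵢ (1 − wᵢ)(p̂ − p̂₋ᵢ)², with p̂₋ᵢ the prediction after removing
record i and renormalizing the remaining weights by 1/(1 − wᵢ). Design
choices:

* **Weights are fixed during jackknifing**: Ĝ is not re-estimated per
  leave-one-out sample. This follows the known-weights simplification under
  which the weighted-mean case collapses exactly to the unbiased sample
  variance Σ(yᵢ − p̂)²/(m(m−1)); re-estimating Ĝ would break that identity.
* Weight-zero records contribute exactly zero (p̂₋ᵢ = p̂) and are skipped —
  no refit is performed for them, and deleting such a record is a no-op for
  both p̂ and the SE.
* A normalized weight numerically ≥ 1 − 1e-12 is an error (the intermediate
  factor 1/(1 − wᵢ) explodes); it cannot occur with two or more non-zero
  weights.
* Multiple query covariate patterns share one leave-one-out sweep; each
  refit is evaluated at all patterns. Pure efficiency, no statistical
  change.
* The unadjusted jackknife Σ ((n−1)/n)(p̂ − p̂₋ᵢ)² is provided for
  comparison; on the tractable example it is the adjusted estimate scaled
  by m/(m−1) · (n−1)/n. The single-jump Greenwood variance d(m−d)/m³ equals
  (m−1)/m times the adjusted variance on the same data.
* The influence-component assumption IF(yᵢ) = (1/wᵢ − 1)(p̂ − p̂₋ᵢ) is
  provable for the weighted mean (where the test suite checks the exact
  identity); for other classifiers it is an assumption, tested empirically
  through SE accuracy and coverage in the simulation harness.
* The delete-d jackknife view of the estimator is a derivation, not a
  separate implementation.

## Confidence intervals

The default interval is computed on the logit scale — bounds
ln(p̂/(1−p̂)) ± z·SE(p̂)/(p̂(1−p̂)) back-transformed by the inverse logit —
and is therefore always inside [0, 1] and contains p̂. A p̂ at 0 or 1 is
clipped to (1e-10, 1 − 1e-10) with a warning so extreme but valid
predictions still get a usable interval. Wald intervals p̂ ± z·SE are
provided unclipped; bounds outside [0, 1] are the documented defect that
motivates the logit form.

## Simulation harness

The generator emulates the reference study conditions: x₁ ∈ {−1, 1} and
x₂ ∈ {0, 1} independent Bernoulli(0.5); event times log-logistic with shape
a = 1 and scale exp(b₀ + b₁x₁ + b₂x₂), b = (1, −0.5, 0.5), drawn by
inverse-CDF t = scale·(u/(1−u))^{1/a}; censoring exponential with rate
λ ∈ {0.017, 0.10, 0.27}, calibrated (verified by numerical integration) to
expected zero-weight fractions of 5%, 25% and 50% at τ = 5. With shape 1
the dichotomized outcome follows a logistic model, so neither the AFT nor
the weighted GLM is misspecified and true probabilities are available in
closed form (p₁₁ = 0.352, p₁₀ = 0.248 at τ = 5). A master seed spawns
independent per-replicate substreams; identical seeds reproduce results
bitwise.

Per replicate each requested method yields predictions per query pattern,
model-based and/or adjusted-jackknife SEs, logit CIs for each SE flavour,
and the in-sample IPC-weighted Brier score. The Brier score is implemented
as Σ wᵢ(p̂ᵢ − yᵢ)² with **normalized** weights, which equals 1/n times the
raw-weight sum (raw weights total ≈ n); the perfectly calibrated limit is
the average of p(1−p) over the four covariate patterns, 0.2261. Summaries
report mean prediction, empirical SD (denominator n_converged − 1; missing
when fewer than two replicates converge), mean SEs, coverage proportions
and mean Brier per (method, pattern).

### Problem sizes

The packaged reproduction runs 500 replicates per cell (the headline
scenarios are n = 1000 and n = 200 at 25% expected zero weights), with the
full jackknife sweep at n = 200 and model-based SEs at n = 1000. At 500
replicates the Monte-Carlo SE of a mean prediction is ≈ 0.0014, of a
coverage proportion ≈ 0.009, and of an SD estimate ≈ 3% relative — adequate
to separate the estimators under comparison. Larger grids and replicate
counts are available through `ipcwjack reproduce-tables --nsim`.

### What passing simulations do and do not show

The generator draws i.i.d. subjects with two balanced binary covariates,
correctly specified models, marginal (covariate-independent) exponential
censoring and a continuous event-time distribution. Passing tests therefore
demonstrate correctness of the weighting algebra, the jackknife estimator
and the interval construction under these conditions. They do not speak to
covariate-dependent censoring (where a marginal Ĝ biases the weights),
model misspecification, heavily tied or interval-recorded times, competing
risks, or high-dimensional covariates — real registry data differ in all of
these respects.

## Known limitations

* Marginal censoring model only; no competing risks, time-dependent
  covariates or interval censoring.
* Model-based GLM covariance ignores the estimation of Ĝ (slightly
  conservative); gradient-boosting results depend on untuned package
  default hyperparameters.
* Jackknife cost is one refit per non-zero-weight subject; for expensive
  learners this scales linearly in n (warm starts mitigate this only for
  the built-in GLM).
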