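"""ADEMP simulation harness for the IPCW-jackknife study conditions.

Data-generating mechanism: two independent Bernoulli(0.5) covariates
(x1 in {-1, 1}, x2 in {0, 1}); event times from a log-logistic distribution
with shape a and scale exp(b0 + b1 x1 + b2 x2); censoring times exponential
with rate lambda_cens (0 means no censoring); the observed time is the
minimum and delta indicates event <= censoring. With shape 1 the
dichotomized outcome at any horizon follows a logistic model, so neither
the AFT comparator nor the weighted logistic classifier is misspecified.

Defaults are the study conditions: b = (1, -0.5, 0.5), shape 1, tau = 5,
lambda_cens in {0.017, 0.10, 0.27} for expected zero-weight fractions of
5%, 25% and 50%.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .classifiers import (
    WeightedClassifierSpec,
    aft_model_se,
    aft_predict_survival,
    fit_loglogistic_aft,
    fit_weighted_logit,
    glm_model_se,
    glm_predict,
    refit_with_weights,
)
from .data import DichotomizedLabels, IPCWeightSet, SurvivalData
from .exceptions import ConfigError, DataError, FitError, WeightUndefinedError
from .ipcw import compute_ipc_weights, dichotomize
from .uncertainty import adjusted_jackknife_se, jackknife_loo_sweep, logit_ci

__all__ = [
    "ScenarioConfig",
    "ADEMPResult",
    "LAMBDA_FOR_PCT_ZERO",
    "true_survival",
    "simulate_dataset",
    "weighted_brier",
    "run_replicate",
    "summarize_ademp",
    "run_scenario",
]

logger = logging.getLogger("ipcwjack.simulation")

#: Exponential censoring rates calibrated to expected zero-weight fractions.
LAMBDA_FOR_PCT_ZERO = {5: 0.017, 25: 0.10, 50: 0.27}

_METHODS = ("aft", "ipcw_glm", "ipcw_plugin")


@dataclass
class ScenarioConfig:
    """One simulation scenario: generating parameters, methods, bookkeeping."""

    n: int
    lambda_cens: float
    nsim: int
    seed: int
    b: tuple[float, float, float] = (1.0, -0.5, 0.5)
    shape: float = 1.0
    tau: float = 5.0
    methods: tuple[str, ...] = ("aft", "ipcw_glm")
    jackknife_methods: tuple[str, ...] = ("ipcw_glm", "ipcw_plugin")
    query_patterns: tuple[tuple[float, float], ...] = ((1.0, 1.0), (1.0, 0.0))
    alpha: float = 0.05
    plugin_spec: WeightedClassifierSpec | None = None

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigError(f"n must be >= 10, got {self.n}")
        if self.nsim < 1:
            raise ConfigError(f"nsim must be >= 1, got {self.nsim}")
        if not self.tau > 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        if self.lambda_cens < 0:
            raise ConfigError(f"lambda_cens must be >= 0, got {self.lambda_cens}")
        if not self.shape > 0:
            raise ConfigError(f"shape must be > 0, got {self.shape}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}; expected subset of {_METHODS}")
        self.b = tuple(float(v) for v in self.b)
        if len(self.b) != 3:
            raise ConfigError("b must have exactly 3 components (b0, b1, b2)")
        self.query_patterns = tuple(tuple(float(v) for v in pat) for pat in self.query_patterns)

    @classmethod
    def from_json(cls, obj: dict) -> "ScenarioConfig":
        valid = {f.name for f in fields(cls)} - {"plugin_spec"}
        unknown = set(obj) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "lambda_cens": self.lambda_cens,
            "nsim": self.nsim,
            "seed": self.seed,
            "b": list(self.b),
            "shape": self.shape,
            "tau": self.tau,
            "methods": list(self.methods),
            "jackknife_methods": list(self.jackknife_methods),
            "query_patterns": [list(p) for p in self.query_patterns],
            "alpha": self.alpha,
        }


def true_survival(x, b, shape: float = 1.0, tau: float = 5.0) -> float:
    """Closed-form P(T* >= tau | x) = (1 + (tau / exp(b'(1,x)))^shape)^-1."""
    if not tau > 0:
        raise DataError(f"tau must be > 0, got {tau}")
    if not shape > 0:
        raise DataError(f"shape must be > 0, got {shape}")
    b = np.asarray(b, dtype=float)
    xt = np.concatenate([[1.0], np.asarray(x, dtype=float).ravel()])
    eta = float(xt @ b)
    return float(expit(shape * (eta - np.log(tau))))


def simulate_dataset(config: ScenarioConfig, replicate_seed: int) -> SurvivalData:
    """Draw one dataset from the generating process, reproducibly per seed."""
    rng = np.random.default_rng(replicate_seed)
    n = config.n
    x1 = rng.integers(0, 2, size=n) * 2.0 - 1.0
    x2 = rng.integers(0, 2, size=n).astype(float)
    b0, b1, b2 = config.b
    scale = np.exp(b0 + b1 * x1 + b2 * x2)
    u = rng.uniform(size=n)
    t_event = scale * (u / (1.0 - u)) ** (1.0 / config.shape)
    t_event = np.maximum(t_event, 1e-300)
    if config.lambda_cens > 0:
        t_cens = rng.exponential(1.0 / config.lambda_cens, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(np.int8)
    return SurvivalData(
        x=np.column_stack([x1, x2]), time=time, status=status, covariate_names=["x1", "x2"]
    )


def weighted_brier(probs, labels: DichotomizedLabels, weights: IPCWeightSet) -> float:
    """IPC-weighted Brier score sum_i w_i (p_i - y_i)^2 with normalized weights.

    Equals the 1/n-scaled sum over raw weights, since raw weights sum to
    about n; weight-zero (UNKNOWN) subjects contribute nothing.
    """
    probs = np.broadcast_to(np.asarray(probs, dtype=float).ravel(), (labels.n,))
    if np.any((probs < 0) | (probs > 1)):
        raise DataError("probabilities must lie in [0, 1]")
    if np.any(~labels.known_mask & (weights.normalized > 0)):
        raise DataError("UNKNOWN outcome with positive weight")
    known = labels.known_mask
    y = labels.y[known].astype(float)
    return float(np.sum(weights.normalized[known] * (probs[known] - y) ** 2))


def run_replicate(config: ScenarioConfig, replicate_seed: int) -> dict:
    """Simulate one dataset and evaluate every requested analysis method.

    Fit failures are recorded per method (``converged=False`` with the error
    message) and never abort the sweep.
    """
    data = simulate_dataset(config, replicate_seed)
    labels = dichotomize(data, config.tau)
    out: dict = {"seed": replicate_seed, "methods": {}}
    try:
        weights = compute_ipc_weights(data, config.tau)
        out["n_zero_weight"] = weights.n_zero
    except (WeightUndefinedError, DataError) as exc:
        out["n_zero_weight"] = None
        for m in config.methods:
            out["methods"][m] = {"converged": False, "error": str(exc), "brier": np.nan, "patterns": {}}
        return out

    query = np.array(config.query_patterns, dtype=float)
    offset = -np.log(config.tau)
    for m in config.methods:
        entry: dict = {"converged": True, "error": None, "brier": np.nan, "patterns": {}}
        try:
            if m == "aft":
                fit = fit_loglogistic_aft(data)
                if not fit.converged:
                    raise FitError("AFT fit did not converge")
                preds = np.atleast_1d(aft_predict_survival(fit, query, config.tau))
                for idx, pat in enumerate(config.query_patterns):
                    p = float(preds[idx])
                    se = aft_model_se(fit, pat, config.tau)
                    entry["patterns"][pat] = {
                        "p_hat": p,
                        "mod_se": se,
                        "jk_se": None,
                        "ci_mod": logit_ci(p, se, config.alpha),
                        "ci_jk": None,
                    }
                probs = aft_predict_survival(fit, data.x, config.tau)
                entry["brier"] = weighted_brier(probs, labels, weights)
            else:
                if m == "ipcw_glm":
                    spec = WeightedClassifierSpec(
                        "weighted_logit", {"offset": offset}, seed=replicate_seed
                    )
                    fit = fit_weighted_logit(data, labels, weights, offset=offset)
                    preds = np.atleast_1d(glm_predict(fit, query))
                    mod_ses = [glm_model_se(fit, pat) for pat in config.query_patterns]
                    probs = glm_predict(fit, data.x)
                else:  # ipcw_plugin
                    spec = config.plugin_spec or WeightedClassifierSpec(
                        "plugin", seed=config.seed
                    )
                    predictor = refit_with_weights(spec, data, labels, weights)
                    preds = np.atleast_1d(predictor(query))
                    mod_ses = [None] * len(config.query_patterns)
                    probs = predictor(data.x)
                jk_ses = [None] * len(config.query_patterns)
                if m in config.jackknife_methods:
                    trace = jackknife_loo_sweep(spec, data, labels, weights, query)
                    jk_arr, _ = adjusted_jackknife_se(
                        spec, data, labels, weights, query, trace=trace
                    )
                    jk_ses = list(np.atleast_1d(jk_arr))
                for idx, pat in enumerate(config.query_patterns):
                    p = float(preds[idx])
                    mod_se = mod_ses[idx]
                    jk_se = jk_ses[idx]
                    entry["patterns"][pat] = {
                        "p_hat": p,
                        "mod_se": mod_se,
                        "jk_se": jk_se,
                        "ci_mod": logit_ci(p, mod_se, config.alpha) if mod_se is not None else None,
                        "ci_jk": logit_ci(p, jk_se, config.alpha) if jk_se is not None else None,
                    }
                entry["brier"] = weighted_brier(probs, labels, weights)
        except (FitError, WeightUndefinedError, DataError) as exc:
            logger.warning("replicate seed=%d method=%s failed: %s", replicate_seed, m, exc)
            entry = {"converged": False, "error": str(exc), "brier": np.nan, "patterns": {}}
        out["methods"][m] = entry
    return out


@dataclass
class ADEMPResult:
    """Per-scenario, per-method, per-pattern simulation summary."""

    table: pd.DataFrame
    truth: dict
    nsim: int
    n_failed: dict
    config: ScenarioConfig | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (method, pattern, metric)."""
        value_cols = [
            c for c in self.table.columns if c not in ("method", "pattern")
        ]
        return self.table.melt(
            id_vars=["method", "pattern"], value_vars=value_cols,
            var_name="metric", value_name="value",
        )


def _ci_covers(ci, truth: float) -> bool:
    return ci is not None and ci[0] <= truth <= ci[1]


def summarize_ademp(
    replicates: Sequence[dict],
    truth: dict,
    alpha: float = 0.05,
    config: ScenarioConfig | None = None,
) -> ADEMPResult:
    """Aggregate replicate results into the performance-measure table.

    Means, empirical SDs (denominator n_converged - 1; reported as missing
    when fewer than two replicates converged) and coverage proportions use
    converged replicates only; excluded replicates are counted per method.
    """
    if not replicates:
        raise FitError("no replicates to summarize")
    methods = list(replicates[0]["methods"])
    patterns = list(truth)
    rows = []
    n_failed = {}
    for m in methods:
        ok = [r["methods"][m] for r in replicates if r["methods"][m]["converged"]]
        n_failed[m] = len(replicates) - len(ok)
        if not ok:
            raise FitError(f"zero converged replicates for method {m!r}")
        briers = np.array([e["brier"] for e in ok])
        for pat in patterns:
            p_true = truth[pat]
            entries = [e["patterns"][pat] for e in ok]
            preds = np.array([e["p_hat"] for e in entries])
            mod = np.array([e["mod_se"] for e in entries if e["mod_se"] is not None], dtype=float)
            jk = np.array([e["jk_se"] for e in entries if e["jk_se"] is not None], dtype=float)
            cov_mod = [_ci_covers(e["ci_mod"], p_true) for e in entries if e["ci_mod"] is not None]
            cov_jk = [_ci_covers(e["ci_jk"], p_true) for e in entries if e["ci_jk"] is not None]
            rows.append(
                {
                    "method": m,
                    "pattern": pat,
                    "true_p": p_true,
                    "mean_prediction": preds.mean(),
                    "empirical_sd": preds.std(ddof=1) if preds.size > 1 else np.nan,
                    "mean_wjk_see": jk.mean() if jk.size else np.nan,
                    "mean_mod_see": mod.mean() if mod.size else np.nan,
                    "coverage_wjk": np.mean(cov_jk) if cov_jk else np.nan,
                    "coverage_mod": np.mean(cov_mod) if cov_mod else np.nan,
                    "mean_brier": briers.mean(),
                    "n_converged": len(ok),
                }
            )
    return ADEMPResult(
        table=pd.DataFrame(rows),
        truth=truth,
        nsim=len(replicates),
        n_failed=n_failed,
        config=config,
    )


def replicate_seeds(master_seed: int, nsim: int) -> list[int]:
    """Independent per-replicate integer seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(nsim)]


def run_scenario(config: ScenarioConfig) -> ADEMPResult:
    """Run all replicates of one scenario and summarize.

    The master seed spawns independent per-replicate substreams; the same
    master seed reproduces the result bitwise.
    """
    seeds = replicate_seeds(config.seed, config.nsim)
    replicates = [run_replicate(config, s) for s in seeds]
    truth = {
        pat: true_survival(pat, config.b, config.shape, config.tau)
        for pat in config.query_patterns
    }
    return summarize_ademp(replicates, truth, alpha=config.alpha, config=config)
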