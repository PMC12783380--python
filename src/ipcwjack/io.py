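"""File I/O and the analyze workflow behind the command line.

Survival CSV dialect: a header row; a ``time`` column (positive floats), a
``status`` column (0/1), and every remaining column a numeric covariate.
UTF-8, "." as decimal separator. Categorical covariates must be pre-encoded
numerically; no silent dummy coding is performed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

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
from .data import SurvivalData
from .exceptions import ConfigError, DataError
from .ipcw import compute_ipc_weights, dichotomize
from .simulation import ADEMPResult, ScenarioConfig
from .uncertainty import adjusted_jackknife_se, jackknife_loo_sweep, logit_ci

__all__ = [
    "read_survival_csv",
    "write_results_csv",
    "read_results_csv",
    "load_scenario_json",
    "format_ademp_table",
    "AnalyzeRequest",
    "run_analyze",
]

#: %.17g survives a text round trip at (better than) 15 significant digits.
_FLOAT_FMT = "%.17g"


def read_survival_csv(path, time_col: str = "time", status_col: str = "status") -> SurvivalData:
    """Read the survival CSV dialect; errors carry 1-based file line numbers."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError, OSError) as exc:
        raise DataError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in (time_col, status_col):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r} (line 1)")

    def _line(row_idx: int) -> int:
        return row_idx + 2  # header is line 1

    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        bad = int(np.argmax(times.isna().to_numpy() | (times <= 0).to_numpy()))
        raise DataError(f"{path}: invalid time {df[time_col].iloc[bad]!r} (line {_line(bad)})")
    status = pd.to_numeric(df[status_col], errors="coerce")
    if status.isna().any() or (~status.isin((0, 1))).any():
        bad = int(np.argmax(status.isna().to_numpy() | (~status.isin((0, 1))).to_numpy()))
        raise DataError(
            f"{path}: status must be 0 or 1, got {df[status_col].iloc[bad]!r} (line {_line(bad)})"
        )
    cov_cols = [c for c in df.columns if c not in (time_col, status_col)]
    if not cov_cols:
        raise DataError(f"{path}: no covariate columns")
    for c in cov_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = int(np.argmax(vals.isna().to_numpy()))
            raise DataError(
                f"{path}: non-numeric covariate {c!r} value {df[c].iloc[bad]!r} "
                f"(line {_line(bad)})"
            )
    return SurvivalData(
        x=df[cov_cols].to_numpy(dtype=float),
        time=times.to_numpy(dtype=float),
        status=status.to_numpy(dtype=int),
        covariate_names=cov_cols,
    )


def write_results_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_scenario_json(path) -> ScenarioConfig:
    """Load a scenario config; unknown keys are rejected by name."""
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, OSError) as exc:
        raise ConfigError(f"{path}: cannot read scenario JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: scenario JSON must be an object")
    return ScenarioConfig.from_json(obj)


def format_ademp_table(result: ADEMPResult) -> str:
    """Fixed-width text rendering of one scenario's performance measures."""
    lines = []
    if result.config is not None:
        c = result.config
        lines.append(
            f"Scenario: n={c.n}  lambda_cens={c.lambda_cens:g}  tau={c.tau:g}  "
            f"nsim={result.nsim}  alpha={c.alpha:g}"
        )
    if result.n_failed:
        failed = ", ".join(f"{m}: {k}" for m, k in result.n_failed.items())
        lines.append(f"Non-converged replicates excluded: {failed}")
    df = result.table.copy()
    df["pattern"] = df["pattern"].map(lambda p: "(" + ",".join(f"{v:g}" for v in p) + ")")
    fmt = {
        "true_p": "{:.3f}".format,
        "mean_prediction": "{:.3f}".format,
        "empirical_sd": "{:.4f}".format,
        "mean_wjk_see": "{:.4f}".format,
        "mean_mod_see": "{:.4f}".format,
        "coverage_wjk": "{:.3f}".format,
        "coverage_mod": "{:.3f}".format,
        "mean_brier": "{:.4f}".format,
    }
    lines.append(df.to_string(index=False, formatters=fmt, na_rep="-"))
    return "\n".join(lines) + "\n"


@dataclass
class AnalyzeRequest:
    """A single prediction-with-uncertainty run on a user CSV."""

    input: str
    tau: float
    method: str = "ipcw_glm"
    se: str = "adjusted_jackknife"
    alpha: float = 0.05
    query: str = "all-rows"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.method not in ("weighted_mean", "ipcw_glm", "ipcw_plugin", "aft"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.se not in ("adjusted_jackknife", "model_based"):
            raise ConfigError(f"unknown se method {self.se!r}")


def _parse_query(query: str, data: SurvivalData) -> np.ndarray:
    if query == "all-rows":
        return np.unique(data.x, axis=0)
    try:
        patterns = [
            [float(v) for v in part.split(",")] for part in query.split(";") if part.strip()
        ]
    except ValueError as exc:
        raise ConfigError(f"cannot parse query {query!r}: {exc}") from exc
    q = np.asarray(patterns, dtype=float)
    if q.ndim != 2 or q.shape[1] != data.p:
        raise ConfigError(
            f"query patterns must have {data.p} covariate values each, got {query!r}"
        )
    return q


def run_analyze(request: AnalyzeRequest) -> pd.DataFrame:
    """Predict survival probabilities at tau with SEs and logit CIs.

    One output row per query covariate pattern with columns: the covariate
    values, p_hat, se, ci_low, ci_high, se_method, n, n_zero_weight,
    pct_zero_weight.
    """
    data = read_survival_csv(request.input)
    labels = dichotomize(data, request.tau)
    weights = compute_ipc_weights(data, request.tau)
    query = _parse_query(request.query, data)
    offset = -np.log(request.tau)

    if request.method == "aft":
        if request.se == "adjusted_jackknife":
            raise ConfigError(
                "the survival model carries no IPC weights; only model_based SEs exist for it"
            )
        fit = fit_loglogistic_aft(data)
        p_hat = np.atleast_1d(aft_predict_survival(fit, query, request.tau))
        ses = np.array([aft_model_se(fit, q, request.tau) for q in query])
    elif request.se == "model_based":
        if request.method != "ipcw_glm":
            raise ConfigError(f"model_based SEs are not available for {request.method!r}")
        fit = fit_weighted_logit(data, labels, weights, offset=offset)
        p_hat = np.atleast_1d(glm_predict(fit, query))
        ses = np.array([glm_model_se(fit, q) for q in query])
    else:
        kind = {"weighted_mean": "weighted_mean", "ipcw_glm": "weighted_logit", "ipcw_plugin": "plugin"}[request.method]
        hyper = {"offset": offset} if kind == "weighted_logit" else {}
        spec = WeightedClassifierSpec(kind, hyper, seed=request.seed)
        trace = jackknife_loo_sweep(spec, data, labels, weights, query)
        ses, trace = adjusted_jackknife_se(spec, data, labels, weights, query, trace=trace)
        ses = np.atleast_1d(ses)
        p_hat = trace.p_hat_full

    rows = []
    for j, q in enumerate(query):
        lo, hi = logit_ci(float(p_hat[j]), float(ses[j]), request.alpha)
        rows.append(
            {
                **{name: q[i] for i, name in enumerate(data.covariate_names)},
                "p_hat": float(p_hat[j]),
                "se": float(ses[j]),
                "ci_low": lo,
                "ci_high": hi,
                "se_method": request.se,
                "n": data.n,
                "n_zero_weight": weights.n_zero,
                "pct_zero_weight": 100.0 * weights.n_zero / data.n,
            }
        )
    return pd.DataFrame(rows)
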