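"""IPCW-adjusted jackknife standard errors and confidence intervals.

For a prediction p-hat fitted on IPC-weighted data with normalized weights
w_i, the adjusted infinitesimal jackknife variance estimate is

    Var(p-hat) = sum_i (1 - w_i) (p-hat - p-hat_{-i})^2,

where p-hat_{-i} is the prediction refitted with record i removed and the
remaining weights renormalized by 1/(1 - w_i). Two adjustments distinguish
this from the classical jackknife: the empirical distribution puts mass w_i
(not 1/n) on record i, and the influence component of record i is taken to
be (1/w_i - 1)(p-hat - p-hat_{-i}). Weight-zero records satisfy
p-hat_{-i} = p-hat exactly and contribute nothing.

The censoring-survival estimate behind the weights is held fixed across
leave-one-out replicates: weights are treated as known functions of the
data, which is the simplification under which the weighted-mean case
reduces exactly to the unbiased sample-variance formula.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .classifiers import (
    WeightedClassifierSpec,
    _design,
    _irls,
    glm_predict,
    refit_with_weights,
    weighted_mean_predict,
)
from .data import DichotomizedLabels, IPCWeightSet, as_survival_data
from .exceptions import ConfigError, DataError, FitError

__all__ = [
    "PredictionWithUncertainty",
    "JackknifeTrace",
    "loo_renormalized_weights",
    "jackknife_loo_sweep",
    "adjusted_jackknife_se",
    "unadjusted_jackknife_se",
    "greenwood_variance",
    "logit_ci",
    "wald_ci",
]

_CI_EPS = 1e-10
_W_MAX = 1.0 - 1e-12  # a single weight this close to 1 makes 1/(1-w) explode


@dataclass
class PredictionWithUncertainty:
    """A point prediction with its standard error and confidence interval."""

    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    se_method: str
    ci_method: str = "logit"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ci_method == "logit":
            if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
                raise DataError("logit interval must lie inside [0, 1]")


@dataclass
class JackknifeTrace:
    """Leave-one-out predictions from one jackknife sweep.

    ``loo_predictions`` has one row per record and one column per query
    covariate pattern; rows of weight-zero records equal the full-sample
    prediction exactly (no refit is performed for them).
    """

    loo_predictions: np.ndarray
    weights_used: IPCWeightSet
    p_hat_full: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Audit table: record index, weight, leave-one-out predictions."""
        loo = np.atleast_2d(self.loo_predictions.T).T
        df = pd.DataFrame(
            {"record": np.arange(loo.shape[0]), "weight": self.weights_used.normalized}
        )
        for k in range(loo.shape[1]):
            df[f"loo_prediction_{k}"] = loo[:, k]
        return df


def loo_renormalized_weights(weights: IPCWeightSet, i: int) -> IPCWeightSet:
    """Weights with record i removed and the rest renormalized by 1/(1-w_i).

    The censoring curve behind the weights is not re-estimated; removing a
    weight-zero record leaves the remaining weights unchanged.
    """
    if not 0 <= i < weights.n:
        raise DataError(f"index {i} out of range for {weights.n} weights")
    if weights.normalized[i] >= _W_MAX:
        raise DataError(f"weight at index {i} is numerically 1; leave-one-out undefined")
    keep = np.ones(weights.n, dtype=bool)
    keep[i] = False
    return IPCWeightSet.from_raw(weights.raw[keep])


def _query_matrix(query_x, p: int) -> tuple[np.ndarray, bool]:
    q = np.asarray(query_x, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != p:
        raise DataError(f"query covariate dimension {q.shape[1]} does not match data ({p})")
    return q, single


def jackknife_loo_sweep(
    spec: WeightedClassifierSpec,
    data,
    labels: DichotomizedLabels,
    weights: IPCWeightSet,
    query_x,
) -> JackknifeTrace:
    """One leave-one-out sweep evaluated at every query covariate pattern.

    Weighted-mean and weighted-logit models use closed-form and
    warm-started IRLS fast paths respectively; any other classifier is
    refitted from scratch on each leave-one-out subsample through
    :func:`refit_with_weights`. All paths produce identical results up to
    solver tolerance.
    """
    data = as_survival_data(data)
    query, _ = _query_matrix(query_x, data.p)
    n, k = data.n, query.shape[0]
    w = weights.normalized
    if np.any(w >= _W_MAX):
        bad = int(np.argmax(w >= _W_MAX))
        raise DataError(f"weight at index {bad} is numerically 1; jackknife undefined")

    predictor = refit_with_weights(spec, data, labels, weights)
    p_full = np.asarray(predictor(query), dtype=float).ravel()
    loo = np.tile(p_full, (n, 1))
    nonzero = np.flatnonzero(~weights.zero_mask)

    if spec.kind == "weighted_mean":
        p0 = p_full[0]
        y = labels.y.astype(float)
        loo_vals = (p0 - w[nonzero] * y[nonzero]) / (1.0 - w[nonzero])
        loo[nonzero, :] = loo_vals[:, None]
    elif spec.kind == "weighted_logit":
        offset = float(spec.hyperparameters.get("offset", 0.0))
        known = labels.known_mask & ~weights.zero_mask
        X = _design(data.x[known])
        y = labels.y[known].astype(float)
        w_known = w[known]
        Xq = _design(query)
        beta_full = predictor.fit_.coefficients
        known_idx = np.flatnonzero(known)
        w_work = w_known.copy()
        for j, i in enumerate(known_idx):
            w_work[j] = 0.0
            beta, conv, _ = _irls(X, y, w_work, offset, start=beta_full)
            w_work[j] = w_known[j]
            if not conv:
                raise FitError(f"leave-one-out refit failed to converge at record {i}")
            loo[i, :] = expit(offset + Xq @ beta)
    else:
        for i in nonzero:
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            loo_weights = loo_renormalized_weights(weights, i)
            loo_labels = DichotomizedLabels(y=labels.y[keep], tau=labels.tau)
            try:
                pred_i = refit_with_weights(spec, data.subset(keep), loo_labels, loo_weights)
            except FitError as exc:
                raise FitError(f"leave-one-out refit failed at record {i}: {exc}") from exc
            loo[i, :] = np.asarray(pred_i(query), dtype=float).ravel()

    return JackknifeTrace(loo_predictions=loo, weights_used=weights, p_hat_full=p_full)


def adjusted_jackknife_se(
    spec: WeightedClassifierSpec,
    data,
    labels: DichotomizedLabels,
    weights: IPCWeightSet,
    query_x,
    trace: JackknifeTrace | None = None,
) -> tuple[np.ndarray | float, JackknifeTrace]:
    """IPCW-adjusted jackknife SE: sqrt(sum_i (1 - w_i)(p-hat - p-hat_{-i})^2)."""
    data = as_survival_data(data)
    query, single = _query_matrix(query_x, data.p)
    if trace is None:
        trace = jackknife_loo_sweep(spec, data, labels, weights, query)
    diff = trace.p_hat_full[None, :] - trace.loo_predictions
    var = np.sum((1.0 - weights.normalized)[:, None] * diff**2, axis=0)
    se = np.sqrt(var)
    return (float(se[0]) if single else se), trace


def unadjusted_jackknife_se(
    spec: WeightedClassifierSpec,
    data,
    labels: DichotomizedLabels,
    weights: IPCWeightSet,
    query_x,
    trace: JackknifeTrace | None = None,
) -> np.ndarray | float:
    """Classical jackknife SE: sqrt(sum_i ((n-1)/n)(p-hat - p-hat_{-i})^2).

    Weight-zero records still contribute zero because their leave-one-out
    prediction equals the full-sample one.
    """
    data = as_survival_data(data)
    query, single = _query_matrix(query_x, data.p)
    if trace is None:
        trace = jackknife_loo_sweep(spec, data, labels, weights, query)
    n = weights.n
    diff = trace.p_hat_full[None, :] - trace.loo_predictions
    var = (n - 1) / n * np.sum(diff**2, axis=0)
    se = np.sqrt(var)
    return float(se[0]) if single else se


def greenwood_variance(m: int, d: int) -> float:
    """Single-jump Greenwood variance d(m - d)/m^3 of a survival estimate.

    ``m`` is the number of subjects at risk (equal non-zero weights 1/m) and
    ``d`` the number of events among them. Equals (m-1)/m times the adjusted
    jackknife variance of the weighted mean on the same data.
    """
    if m < 1:
        raise DataError(f"m must be >= 1, got {m}")
    if not 0 <= d <= m:
        raise DataError(f"d must lie in [0, {m}], got {d}")
    return d * (m - d) / m**3


def _check_alpha(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return norm.ppf(1.0 - alpha / 2.0)


def logit_ci(p_hat: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Confidence interval computed on the logit scale and back-transformed.

    The delta method gives SE(logit p-hat) = SE(p-hat) / (p-hat (1 - p-hat));
    the resulting interval always lies inside [0, 1] and contains p-hat.
    A p-hat at 0 or 1 is clipped to (1e-10, 1 - 1e-10) with a warning.
    """
    z = _check_alpha(alpha)
    if se < 0:
        raise DataError(f"se must be >= 0, got {se}")
    if not _CI_EPS < p_hat < 1.0 - _CI_EPS:
        warnings.warn(
            f"p_hat={p_hat:g} clipped to the open unit interval for the logit CI",
            stacklevel=2,
        )
        p_hat = float(np.clip(p_hat, _CI_EPS, 1.0 - _CI_EPS))
    if se == 0.0:
        return (p_hat, p_hat)
    half = z * se / (p_hat * (1.0 - p_hat))
    center = logit(p_hat)
    return (float(expit(center - half)), float(expit(center + half)))


def wald_ci(p_hat: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Wald interval p-hat +/- z * se; deliberately not clipped to [0, 1].

    Bounds outside the unit interval are the known defect of this interval
    for probabilities; callers may clip, the logit interval avoids it.
    """
    z = _check_alpha(alpha)
    if se < 0:
        raise DataError(f"se must be >= 0, got {se}")
    return (float(p_hat - z * se), float(p_hat + z * se))
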