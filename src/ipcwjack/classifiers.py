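"""IPC-weighted prediction models with a common refit-with-weights contract.

All classifiers here minimize the IPC-weighted binary log loss

    loss_w = -sum_i w_i [ I(y_i = 1) ln p_i + I(y_i = 0) ln(1 - p_i) ]

over the subjects whose dichotomized outcome is observable (weight-zero
subjects contribute nothing). Minimizing this loss in expectation recovers
the true conditional survival probability P(T* >= tau | X = x), which is
what makes IPC-weighted classification unbiased.

Three concrete models are provided: the weighted mean (covariate-free), a
weighted logistic GLM with a fixed offset in the linear predictor, and a
log-logistic accelerated-failure-time model fitted on the raw censored
times as a survival-analysis comparator. A plugin slot adapts any
scikit-learn-style classifier that honours per-record ``sample_weight``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

from .data import DichotomizedLabels, IPCWeightSet, as_survival_data
from .exceptions import ConfigError, DataError, FitError

__all__ = [
    "WeightedClassifierSpec",
    "GLMFit",
    "AFTFit",
    "weighted_mean_predict",
    "weighted_log_loss",
    "fit_weighted_logit",
    "glm_predict",
    "glm_model_se",
    "fit_loglogistic_aft",
    "aft_predict_survival",
    "aft_model_se",
    "refit_with_weights",
]

_LOSS_EPS = 1e-10  # probability clipping for loss evaluation only

_KINDS = ("weighted_mean", "weighted_logit", "plugin")


@dataclass
class WeightedClassifierSpec:
    """Serializable description of an IPC-weighted classifier.

    ``hyperparameters`` are passed through to the concrete model (for the
    weighted logit, the key ``offset`` fixes the linear-predictor offset;
    for plugins they are estimator parameters). ``plugin_factory`` is an
    optional callable ``(hyperparameters, seed) -> estimator`` with sklearn
    fit/predict_proba semantics; when absent, a small deterministic
    gradient-boosting model is used for ``kind='plugin'``.
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    plugin_factory: Callable | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}; expected one of {_KINDS}")

    def to_json(self) -> dict:
        return {"kind": self.kind, "hyperparameters": dict(self.hyperparameters), "seed": self.seed}

    @classmethod
    def from_json(cls, obj: dict) -> "WeightedClassifierSpec":
        return cls(kind=obj["kind"], hyperparameters=dict(obj.get("hyperparameters", {})), seed=int(obj.get("seed", 0)))


@dataclass
class GLMFit:
    """Weighted logistic fit: coefficients (intercept first), robust
    (sandwich) coefficient covariance, and the fixed offset added to the
    linear predictor."""

    coefficients: np.ndarray
    covariance: np.ndarray
    offset: float
    converged: bool
    iterations: int


@dataclass
class AFTFit:
    """Log-logistic AFT fit.

    ``coefficients`` are the location coefficients b (intercept first) so
    the scale is exp(b'(1, x)); ``shape`` is the positive shape parameter a;
    ``covariance`` is over the stacked parameter vector (b0..bp, log a).
    """

    shape: float
    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool


def _check_weighted_labels(labels: DichotomizedLabels, weights: IPCWeightSet) -> None:
    if labels.n != weights.n:
        raise DataError("labels and weights have different lengths")
    if np.any(~labels.known_mask & (weights.normalized > 0)):
        bad = int(np.argmax(~labels.known_mask & (weights.normalized > 0)))
        raise DataError(f"UNKNOWN outcome with positive weight at index {bad}")


def weighted_mean_predict(labels: DichotomizedLabels, weights: IPCWeightSet) -> float:
    """The IPC-weighted mean of the dichotomized outcomes, sum_k w_k y_k."""
    _check_weighted_labels(labels, weights)
    known = labels.known_mask
    return float(np.sum(weights.normalized[known] * labels.y[known]))


def weighted_log_loss(probs, labels: DichotomizedLabels, weights: IPCWeightSet) -> float:
    """IPC-weighted binary log loss with normalized weights.

    Probabilities are clipped to (1e-10, 1 - 1e-10) for evaluation; an exact
    0 or 1 with a discordant observed label is an error rather than an
    infinite loss.
    """
    _check_weighted_labels(labels, weights)
    probs = np.broadcast_to(np.asarray(probs, dtype=float).ravel(), (labels.n,))
    known = labels.known_mask
    y = labels.y[known].astype(float)
    p = probs[known]
    w = weights.normalized[known]
    discordant = ((p <= 0) & (y == 1)) | ((p >= 1) & (y == 0))
    if np.any(discordant):
        raise DataError("probability 0 or 1 with discordant label; loss is infinite")
    p = np.clip(p, _LOSS_EPS, 1 - _LOSS_EPS)
    return float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def _design(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.hstack([np.ones((x.shape[0], 1)), x])


def _logit_loss(X: np.ndarray, y: np.ndarray, w: np.ndarray, offset: float, beta: np.ndarray) -> float:
    eta = offset + X @ beta
    return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    offset: float,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool, int]:
    """Iteratively reweighted least squares with step-halving.

    Convergence: relative coefficient change below ``tol``. The iterate path
    is invariant to rescaling ``w`` by a positive constant, so fits with raw
    and normalized weights coincide exactly.
    """
    beta = np.zeros(X.shape[1]) if start is None else np.array(start, dtype=float)
    cur = _logit_loss(X, y, w, offset, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = offset + X @ beta
        mu = expit(eta)
        wv = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * wv[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        scale = 1.0
        new_loss = cur
        for _ in range(30):
            cand = beta + scale * step
            new_loss = _logit_loss(X, y, w, offset, cand)
            if new_loss <= cur + 1e-15:
                break
            scale *= 0.5
        beta_new = beta + scale * step
        rel = np.max(np.abs(beta_new - beta)) / (np.max(np.abs(beta_new)) + 1.0)
        beta, cur = beta_new, new_loss
        if rel < tol:
            converged = True
            break
    return beta, converged, it


def fit_weighted_logit(
    data,
    labels: DichotomizedLabels,
    weights: IPCWeightSet,
    offset: float = 0.0,
    start: np.ndarray | None = None,
) -> GLMFit:
    """Maximize the IPC-weighted binomial log-likelihood with a fixed offset.

    The coefficient covariance is the robust (sandwich) variance
    A^-1 B A^-1 of the weighted score equations, with A the raw-weight
    observed information and B the outer product of the raw-weight score
    contributions. Because IPC weights vary across subjects, the weighted
    score terms are over-dispersed relative to the information, and the
    plain inverse information understates prediction variance; the sandwich
    restores the correct scale while still treating the censoring weights
    as fixed.
    """
    data = as_survival_data(data)
    _check_weighted_labels(labels, weights)
    known = labels.known_mask & ~weights.zero_mask
    n_eff = int(known.sum())
    if n_eff < data.p + 2:
        raise FitError(f"only {n_eff} records with non-zero weight; need >= {data.p + 2}")
    y = labels.y[known].astype(float)
    if y.min() == y.max():
        raise FitError("single-class labels among non-zero-weight records")
    X = _design(data.x[known])
    w_norm = weights.normalized[known]
    beta, converged, it = _irls(X, y, w_norm, offset, start=start)
    if not converged:
        raise FitError(f"IRLS did not converge in {it} iterations (possible separation)")
    mu = expit(offset + X @ beta)
    w_raw = weights.raw[known]
    info = X.T @ (X * (w_raw * mu * (1.0 - mu))[:, None])
    meat = X.T @ (X * ((w_raw * (y - mu)) ** 2)[:, None])
    # pinv tolerates degenerate designs (e.g. a constant covariate column)
    info_inv = np.linalg.pinv(info, hermitian=True)
    cov = info_inv @ meat @ info_inv
    cov = 0.5 * (cov + cov.T)
    return GLMFit(coefficients=beta, covariance=cov, offset=float(offset), converged=converged, iterations=it)


def glm_predict(fit: GLMFit, x) -> np.ndarray | float:
    """Inverse-logit of offset + b'(1, x); x may be a vector or a matrix."""
    x_arr = np.asarray(x, dtype=float)
    single = x_arr.ndim == 1
    X = _design(x_arr)
    if X.shape[1] != fit.coefficients.shape[0]:
        raise DataError(
            f"covariate dimension {X.shape[1] - 1} does not match fit "
            f"({fit.coefficients.shape[0] - 1})"
        )
    out = expit(fit.offset + X @ fit.coefficients)
    return float(out[0]) if single else out


def glm_model_se(fit: GLMFit, x) -> float:
    """Delta-method SE of the predicted probability at covariate vector x."""
    if not fit.converged:
        raise FitError("model-based SE requires a converged fit")
    x_arr = np.asarray(x, dtype=float).ravel()
    xt = np.concatenate([[1.0], x_arr])
    p = expit(fit.offset + xt @ fit.coefficients)
    g = p * (1.0 - p) * xt
    return float(np.sqrt(g @ fit.covariance @ g))


def fit_loglogistic_aft(data) -> AFTFit:
    """Censored maximum-likelihood fit of the log-logistic AFT model.

    The event-time density enters for observed events and the survival
    function for censored subjects. Fitting is delegated to lifelines'
    ``LogLogisticAFTFitter``; its location coefficients and log-shape (with
    their joint covariance) are re-packed into :class:`AFTFit`.
    """
    data = as_survival_data(data)
    if int(data.status.sum()) == 0:
        raise FitError("all observations censored; AFT model is not identifiable")
    df = data.to_dataframe()
    from lifelines import LogLogisticAFTFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    fitter = LogLogisticAFTFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(df, duration_col="time", event_col="status")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"log-logistic AFT fit failed: {exc}") from exc
    converged = not any(issubclass(c.category, ConvergenceWarning) for c in caught)

    order = [("alpha_", "Intercept")] + [("alpha_", name) for name in data.covariate_names]
    coeffs = fitter.params_.reindex(order).to_numpy()
    log_shape = float(fitter.params_[("beta_", "Intercept")])
    full_order = order + [("beta_", "Intercept")]
    cov = fitter.variance_matrix_.reindex(index=full_order, columns=full_order).to_numpy()
    cov = 0.5 * (cov + cov.T)
    return AFTFit(shape=float(np.exp(log_shape)), coefficients=coeffs, covariance=cov, converged=converged)


def aft_predict_survival(fit: AFTFit, x, tau: float) -> np.ndarray | float:
    """S(tau | x) = (1 + (tau / exp(b'(1,x)))^a)^-1 for the fitted model."""
    if not tau > 0:
        raise DataError(f"tau must be > 0, got {tau}")
    x_arr = np.asarray(x, dtype=float)
    single = x_arr.ndim == 1
    X = _design(x_arr)
    eta = X @ fit.coefficients
    out = expit(fit.shape * (eta - np.log(tau)))
    return float(out[0]) if single else out


def aft_model_se(fit: AFTFit, x, tau: float) -> float:
    """Delta-method SE of S(tau | x) over the (b, log a) covariance."""
    if not fit.converged:
        raise FitError("model-based SE requires a converged fit")
    x_arr = np.asarray(x, dtype=float).ravel()
    xt = np.concatenate([[1.0], x_arr])
    eta = float(xt @ fit.coefficients)
    z = fit.shape * (eta - np.log(tau))
    s = expit(z)
    # dS/db_j = s(1-s) a x_j ; dS/d(log a) = s(1-s) a (eta - ln tau)
    g = s * (1.0 - s) * fit.shape * np.concatenate([xt, [eta - np.log(tau)]])
    return float(np.sqrt(g @ fit.covariance @ g))


def _default_plugin_factory(hyperparameters: dict, seed: int):
    from xgboost import XGBClassifier

    params = dict(
        max_depth=2,
        n_estimators=100,
        learning_rate=0.1,
        tree_method="exact",
        n_jobs=1,
        random_state=int(seed) % (2**31),
        objective="binary:logistic",
        eval_metric="logloss",
        base_score=0.5,
    )
    params.update(hyperparameters)
    return XGBClassifier(**params)


def refit_with_weights(
    spec: WeightedClassifierSpec,
    data,
    labels: DichotomizedLabels,
    weights: IPCWeightSet,
    start: np.ndarray | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the classifier described by ``spec`` and return a predictor.

    The returned callable maps a covariate vector or matrix to predicted
    survival probabilities in [0, 1]. Weight-zero (UNKNOWN) records do not
    influence the fit. The result is deterministic for fixed
    (spec, data, weights, seed). ``start`` optionally warm-starts iterative
    fits (used by the leave-one-out jackknife sweep).
    """
    data = as_survival_data(data)
    _check_weighted_labels(labels, weights)
    if spec.kind == "weighted_mean":
        p_hat = weighted_mean_predict(labels, weights)

        def predict_const(x):
            x_arr = np.asarray(x, dtype=float)
            if x_arr.ndim == 1:
                return p_hat
            return np.full(x_arr.shape[0], p_hat)

        predict_const.fit_ = p_hat
        return predict_const
    if spec.kind == "weighted_logit":
        offset = float(spec.hyperparameters.get("offset", 0.0))
        fit = fit_weighted_logit(data, labels, weights, offset=offset, start=start)

        def predict_glm(x):
            return glm_predict(fit, x)

        predict_glm.fit_ = fit
        return predict_glm
    # plugin
    factory = spec.plugin_factory or _default_plugin_factory
    est = factory(dict(spec.hyperparameters), spec.seed)
    known = labels.known_mask & ~weights.zero_mask
    est.fit(data.x[known], labels.y[known].astype(int), sample_weight=weights.raw[known])

    def predict_plugin(x):
        x_arr = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.asarray(est.predict_proba(x_arr))[:, 1]
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    predict_plugin.fit_ = est
    return predict_plugin
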