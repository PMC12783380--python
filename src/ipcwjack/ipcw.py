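"""Dichotomization at a horizon and IPC-weight machinery.

Censoring makes the binary outcome Y = I(T* >= tau) unobservable for
subjects censored before both tau and their event. Inverse-probability-of-
censoring (IPC) weighting assigns those subjects weight zero and re-weights
the remaining ones by 1/G(.), where G(u) = P(C > u) is the censoring
survival function estimated by a reverse Kaplan-Meier (product-limit with
the roles of event and censoring swapped).
"""
from __future__ import annotations

import numpy as np

from .data import (
    UNKNOWN,
    DichotomizedLabels,
    IPCWeightSet,
    StepSurvivalCurve,
    SurvivalData,
    as_survival_data,
)
from .exceptions import DataError, WeightUndefinedError

__all__ = [
    "dichotomize",
    "reverse_km_censoring",
    "evaluate_survival",
    "compute_ipc_weights",
    "tractable_example_sample",
]


def dichotomize(data, tau: float) -> DichotomizedLabels:
    """Label each subject as survived tau (1), event before tau (0), or UNKNOWN.

    A follow-up time of exactly ``tau`` counts as surviving, regardless of
    the event indicator: I(T* >= tau) is observed whenever T >= tau.
    """
    data = as_survival_data(data)
    if not tau > 0:
        raise DataError(f"tau must be > 0, got {tau}")
    y = np.full(data.n, UNKNOWN, dtype=np.int8)
    y[data.time >= tau] = 1
    y[(data.time < tau) & (data.status == 1)] = 0
    return DichotomizedLabels(y=y, tau=float(tau))


def reverse_km_censoring(data) -> StepSurvivalCurve:
    """Product-limit estimate of the censoring survival G(u) = P(C > u).

    Censorings (delta = 0) are the "events" here and observed events are the
    "censorings". At tied times, events are ordered before censorings within
    the risk set: a subject with an event at u is still at risk for a
    censoring jump at u, so the risk set at u is {i : t_i >= u}.
    """
    data = as_survival_data(data)
    cens_times = data.time[data.status == 0]
    if cens_times.size == 0:
        return StepSurvivalCurve(jump_times=np.empty(0), values=np.empty(0))
    jump_times, d = np.unique(cens_times, return_counts=True)
    # risk set at u_j: all subjects with t >= u_j (events at u_j included)
    time_sorted = np.sort(data.time)
    n_risk = data.n - np.searchsorted(time_sorted, jump_times, side="left")
    values = np.cumprod(1.0 - d / n_risk)
    return StepSurvivalCurve(jump_times=jump_times, values=values)


def evaluate_survival(curve: StepSurvivalCurve, t) -> np.ndarray | float:
    """Right-continuous evaluation of a step survival curve at t >= 0."""
    return curve(t)


def compute_ipc_weights(
    data,
    tau: float,
    censoring_curve: StepSurvivalCurve | None = None,
) -> IPCWeightSet:
    """IPC weights at horizon tau.

    Raw weight is 0 for UNKNOWN subjects, 1/G(tau) for subjects with
    t >= tau, and 1/G(t_i) for events observed before tau; normalized
    weights divide by the raw-weight sum. ``censoring_curve`` defaults to
    the reverse Kaplan-Meier estimate on ``data``.

    Raises
    ------
    WeightUndefinedError
        If G is zero at a required evaluation point.
    """
    data = as_survival_data(data)
    labels = dichotomize(data, tau)
    if censoring_curve is None:
        censoring_curve = reverse_km_censoring(data)
    raw = np.zeros(data.n)

    survived = labels.y == 1
    if np.any(survived):
        g_tau = censoring_curve(tau)
        if g_tau <= 0:
            raise WeightUndefinedError(tau)
        raw[survived] = 1.0 / g_tau

    early_event = labels.y == 0
    if np.any(early_event):
        g_event = np.asarray(censoring_curve(data.time[early_event]), dtype=float)
        if np.any(g_event <= 0):
            bad = data.time[early_event][np.argmax(g_event <= 0)]
            raise WeightUndefinedError(bad)
        raw[early_event] = 1.0 / g_event

    return IPCWeightSet.from_raw(raw)


def tractable_example_sample(
    p: float, q: float, n: int, seed: int
) -> SurvivalData:
    """Two-point event/censoring sample for the analytically tractable setup.

    Event times are 0.75 with probability 1-p and 1.25 with probability p;
    censoring times are 0.5 with probability 1-q and 2 with probability q.
    The observed time is the minimum and delta indicates event <= censoring.
    At horizon tau = 1 the subjects censored at 0.5 are exactly the
    weight-zero ones, and all others receive equal normalized weight 1/m.
    A constant covariate column is attached (the weighted mean ignores it).
    """
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise DataError(f"p and q must lie in [0, 1], got p={p}, q={q}")
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    t_event = np.where(rng.uniform(size=n) < p, 1.25, 0.75)
    t_cens = np.where(rng.uniform(size=n) < q, 2.0, 0.5)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(np.int8)
    return SurvivalData(x=np.zeros((n, 1)), time=time, status=status)
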