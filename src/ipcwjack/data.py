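"""Core containers for right-censored survival classification.

A dataset is one row per subject: a covariate vector ``x``, a follow-up time
``t > 0`` and an event indicator ``delta`` (1 = the event was observed at
``t``, 0 = the subject was censored at ``t``). The observed time is the
minimum of the latent event time and the latent censoring time; neither
latent variable is stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Label for subjects censored before both the horizon and their event: the
#: dichotomized outcome is unobservable for them.
UNKNOWN: int = -1


@dataclass(frozen=True)
class SurvivalRecord:
    """A single subject's covariates, follow-up time and event indicator."""

    x: tuple[float, ...]
    t: float
    delta: int


@dataclass
class SurvivalData:
    """Column-oriented right-censored sample.

    Parameters
    ----------
    x
        Covariate matrix of shape ``(n, p)``; a 1-D array is treated as a
        single covariate column.
    time
        Follow-up times, strictly positive.
    status
        Event indicators in {0, 1}.
    covariate_names
        Optional column names; defaults to ``x1 .. xp``.
    """

    x: np.ndarray
    time: np.ndarray
    status: np.ndarray
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim == 1:
            x = x.reshape(-1, 1)
        if x.ndim != 2:
            raise DataError(f"covariates must be 2-D, got shape {x.shape}")
        time = np.asarray(self.time, dtype=float).ravel()
        status = np.asarray(self.status).ravel()
        if not (x.shape[0] == time.shape[0] == status.shape[0]):
            raise DataError(
                f"length mismatch: x has {x.shape[0]} rows, time {time.shape[0]}, "
                f"status {status.shape[0]}"
            )
        if time.shape[0] == 0:
            raise DataError("empty dataset")
        if not np.all(np.isfinite(x)):
            raise DataError("covariates must be finite")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            bad = int(np.argmax(~(np.isfinite(time) & (time > 0))))
            raise DataError(f"follow-up times must be finite and > 0 (row {bad})")
        if not np.all(np.isin(status, (0, 1))):
            bad = int(np.argmax(~np.isin(status, (0, 1))))
            raise DataError(f"status must be 0 or 1 (row {bad})")
        self.x = x
        self.time = time
        self.status = status.astype(np.int8)
        if self.covariate_names is None:
            self.covariate_names = [f"x{j + 1}" for j in range(x.shape[1])]
        elif len(self.covariate_names) != x.shape[1]:
            raise DataError("covariate_names length does not match covariate count")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @classmethod
    def from_records(cls, records: Iterable[SurvivalRecord]) -> "SurvivalData":
        records = list(records)
        if not records:
            raise DataError("empty dataset")
        dims = {len(r.x) for r in records}
        if len(dims) != 1:
            raise DataError(f"inconsistent covariate dimensions: {sorted(dims)}")
        return cls(
            x=np.array([r.x for r in records], dtype=float),
            time=np.array([r.t for r in records], dtype=float),
            status=np.array([r.delta for r in records]),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        status_col: str = "status",
    ) -> "SurvivalData":
        for col in (time_col, status_col):
            if col not in df.columns:
                raise DataError(f"missing required column {col!r}")
        cov_cols = [c for c in df.columns if c not in (time_col, status_col)]
        if not cov_cols:
            raise DataError("no covariate columns found")
        try:
            x = df[cov_cols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-numeric covariate column: {exc}") from exc
        return cls(
            x=x,
            time=df[time_col].to_numpy(dtype=float),
            status=df[status_col].to_numpy(),
            covariate_names=cov_cols,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=self.covariate_names)
        df.insert(0, "time", self.time)
        df.insert(1, "status", self.status)
        return df

    def subset(self, idx) -> "SurvivalData":
        """Row subset (boolean mask or integer indices)."""
        idx = np.asarray(idx)
        return SurvivalData(
            x=self.x[idx],
            time=self.time[idx],
            status=self.status[idx],
            covariate_names=list(self.covariate_names),
        )


def as_survival_data(obj) -> SurvivalData:
    """Coerce a SurvivalData, list of SurvivalRecord, or DataFrame."""
    if isinstance(obj, SurvivalData):
        return obj
    if isinstance(obj, pd.DataFrame):
        return SurvivalData.from_dataframe(obj)
    return SurvivalData.from_records(obj)


@dataclass
class DichotomizedLabels:
    """Trichotomous labels at a fixed horizon tau.

    ``y[i]`` is 1 if subject i is known to survive tau (t >= tau), 0 if an
    event was observed before tau, and :data:`UNKNOWN` (-1) if the subject
    was censored before both tau and an event.
    """

    y: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8).ravel()
        if not np.all(np.isin(self.y, (0, 1, UNKNOWN))):
            raise DataError("labels must be 0, 1 or UNKNOWN")
        if not self.tau > 0:
            raise DataError(f"tau must be > 0, got {self.tau}")

    @property
    def known_mask(self) -> np.ndarray:
        return self.y != UNKNOWN

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class StepSurvivalCurve:
    """Right-continuous step estimate of a survival function.

    The value is 1 before the first jump; at and after the j-th jump time it
    is ``values[j]``. Used for the censoring-survival estimate G(u) = P(C > u)
    and, with roles swapped, for the Kaplan-Meier event-survival estimate.
    """

    jump_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.jump_times.shape != self.values.shape:
            raise DataError("jump_times and values must have equal length")
        if self.jump_times.size:
            if np.any(np.diff(self.jump_times) <= 0):
                raise DataError("jump_times must be strictly increasing")
            if np.any(self.jump_times <= 0):
                raise DataError("jump_times must be positive")
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise DataError("survival values must lie in [0, 1]")
            if np.any(np.diff(self.values) > 1e-15):
                raise DataError("survival values must be non-increasing")

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate S(t), right-continuously, for scalar or array t."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise DataError("evaluation times must be >= 0")
        idx = np.searchsorted(self.jump_times, t_arr, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)] if self.values.size else 1.0, 1.0)
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(out)
        return out


@dataclass
class IPCWeightSet:
    """Raw and normalized inverse-probability-of-censoring weights.

    ``raw[i]`` is 0 for subjects whose dichotomized outcome is unobservable,
    1/G(tau) for subjects with t >= tau and 1/G(t_i) for events before tau.
    ``normalized`` divides by the raw sum (so it sums to 1); ``zero_mask``
    marks the weight-zero subjects.
    """

    raw: np.ndarray
    normalized: np.ndarray
    zero_mask: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float).ravel()
        self.normalized = np.asarray(self.normalized, dtype=float).ravel()
        self.zero_mask = np.asarray(self.zero_mask, dtype=bool).ravel()
        if not (self.raw.shape == self.normalized.shape == self.zero_mask.shape):
            raise DataError("weight components must have equal length")
        if np.any(self.raw < 0):
            raise DataError("raw weights must be non-negative")

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "IPCWeightSet":
        raw = np.asarray(raw, dtype=float).ravel()
        total = raw.sum()
        if total <= 0:
            raise DataError("all raw weights are zero; weights are undefined")
        return cls(raw=raw, normalized=raw / total, zero_mask=raw == 0)

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def n_zero(self) -> int:
        return int(self.zero_mask.sum())
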