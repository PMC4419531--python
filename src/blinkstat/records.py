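"""Core record types shared by the simulation and analysis layers.

Lags are always expressed as target onset asynchrony (TOA) in units of
100 ms, so a 300 ms TOA is lag 3.0 and a 50 ms TOA is lag 0.5.  One
parameterization of every curve model therefore covers both the slow
(100 ms SOA) and fast (50 ms SOA) presentation protocols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "as_lag_grid",
    "MeanCurve",
    "SubjectLagCurve",
    "TrialRecord",
    "TRIAL_CSV_COLUMNS",
    "TRUTH_CSV_COLUMNS",
]


def as_lag_grid(lags: Sequence[float]) -> np.ndarray:
    """Validate and return a lag grid: strictly increasing positive reals."""
    arr = np.asarray(lags, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DataError("lag grid must be a non-empty 1-D sequence")
    if not np.all(arr > 0):
        raise DataError("all lags must be > 0")
    if not np.all(np.diff(arr) > 0):
        raise DataError("lags must be strictly increasing")
    return arr


@dataclass(frozen=True)
class MeanCurve:
    """A per-lag curve of mean values (accuracy or swap probability)."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lags", as_lag_grid(self.lags))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.lags.shape:
            raise DataError("values must have one entry per lag")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.lags.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_100ms": self.lags, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeanCurve":
        df = pd.read_csv(path)
        expected = ["lag_100ms", "value"]
        if list(df.columns) != expected:
            bad = next(
                (c for c, e in zip(df.columns, expected) if c != e),
                df.columns[0] if len(df.columns) else "<none>",
            )
            raise DataError(
                f"curve CSV header must be {expected}; first bad column: {bad!r}"
            )
        return cls(df["lag_100ms"].to_numpy(), df["value"].to_numpy())

    def to_json(self) -> str:
        return json.dumps({"lags": self.lags.tolist(), "values": self.values.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MeanCurve":
        obj = json.loads(text)
        return cls(np.asarray(obj["lags"]), np.asarray(obj["values"]))


@dataclass(frozen=True)
class SubjectLagCurve:
    """One subject's per-lag response profile.

    ``pr_t1`` is the probability of reporting the first target, the
    baseline perceptual measure.  ``pr_t2_given_t1`` is second-target
    accuracy conditional on a correct first-target report (the attentional
    blink measure).  ``pr_swap`` is the probability of reporting both
    targets but in reversed temporal order (the temporal-integration
    measure); a swap requires both targets to be reported, so
    ``pr_swap <= pr_t1`` at every lag.
    """

    subject_id: str
    group: str
    lags: np.ndarray
    pr_t1: np.ndarray
    pr_t2_given_t1: np.ndarray
    pr_swap: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lags", as_lag_grid(self.lags))
        for name in ("pr_t1", "pr_t2_given_t1", "pr_swap"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.lags.shape:
                raise DataError(f"{name} must have one entry per lag")
            object.__setattr__(self, name, arr)
        if np.any(self.pr_swap > self.pr_t1 + 1e-12):
            raise DataError("pr_swap may not exceed pr_t1 (a swap needs both targets)")

    def measure(self, name: str) -> np.ndarray:
        """Return one of the per-lag measures by name."""
        if name not in ("pr_t1", "pr_t2_given_t1", "pr_swap"):
            raise DataError(f"unknown measure {name!r}")
        return getattr(self, name)


TRIAL_CSV_COLUMNS = [
    "subject_id",
    "group",
    "trial_index",
    "condition",
    "toa_ms",
    "t1",
    "t2",
    "t3",
    "report_1",
    "report_2",
    "report_3",
]

TRUTH_CSV_COLUMNS = [
    "subject_id",
    "group",
    "lag_100ms",
    "pr_t1",
    "pr_t2_given_t1",
    "pr_swap",
]


@dataclass(frozen=True)
class TrialRecord:
    """One RSVP trial: targets shown and the ordered report."""

    subject_id: str
    group: str
    trial_index: int
    condition: str  # "dual" | "triple"
    toa_ms: int
    t1: str
    t2: str
    t3: str = ""  # only on triple-target trials (800 ms after T2)
    reported: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.condition not in ("dual", "triple"):
            raise DataError(f"condition must be dual|triple, got {self.condition!r}")
        if self.condition == "triple" and not self.t3:
            raise DataError("triple-target trials must carry a third target")
        if self.condition == "dual" and self.t3:
            raise DataError("dual-target trials may not carry a third target")
        if self.t1 == self.t2:
            raise DataError("T1 and T2 identities must differ")
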