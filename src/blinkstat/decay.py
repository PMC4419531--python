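"""Decay-law models of temporal order (swap) errors.

Swap probability as a function of lag ``x`` (TOA / 100 ms) is described
by one of two two-parameter decay laws that share a decay rate ``a`` and
a long-lag baseline ``b``:

    exponential decay (EDF):  Pr(x) = b + exp(-a * x)
    logistic decay    (LDF):  Pr(x) = b + 1 / (1 + exp(a * x))

Both converge to ``b`` as ``x`` grows; at ``x = 0`` the EDF anchors at
``b + 1`` and the LDF at ``b + 0.5``.  Because both have exactly two
parameters, raw mean-squared error is the model-selection criterion —
no flexibility correction is needed.

The module fits either law to mean swap curves (multistart bounded
least squares), compares the two per group, extracts per-subject decay
rates, and correlates those rates with clinical scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, FitError, ParameterError
from .records import MeanCurve, SubjectLagCurve

__all__ = [
    "DecayParams",
    "DecayFit",
    "decay_value",
    "fit_decay",
    "compare_decay_models",
    "subject_decay_rates",
    "CorrelationResult",
    "correlate_decay_with_clinical",
    "DECAY_RATE_BOUNDS",
    "BASELINE_BOUNDS",
    "MULTISTART_RATES",
]

KINDS = ("ldf", "edf")
#: Fit bounds: swap baselines above 0.5 are behaviorally meaningless.
DECAY_RATE_BOUNDS = (1e-6, 10.0)
BASELINE_BOUNDS = (0.0, 0.5)
MULTISTART_RATES = (0.5, 1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class DecayParams:
    decay_rate: float
    baseline: float

    def __post_init__(self):
        if self.decay_rate <= 0:
            raise ParameterError("decay_rate must be > 0")
        if not (0.0 <= self.baseline < 1.0):
            raise ParameterError("baseline must lie in [0, 1)")


@dataclass(frozen=True)
class DecayFit:
    kind: str
    params: DecayParams
    mse: float
    lags_used: np.ndarray


def _check_kind(kind: str) -> str:
    k = kind.lower()
    if k not in KINDS:
        raise ParameterError(f"kind must be one of {KINDS}, got {kind!r}")
    return k


def decay_value(kind: str, params: DecayParams, x) -> np.ndarray | float:
    """Evaluate a decay law at lag(s) ``x``."""
    kind = _check_kind(kind)
    x = np.asarray(x, float)
    if kind == "edf":
        out = params.baseline + np.exp(-params.decay_rate * x)
    else:
        out = params.baseline + 1.0 / (1.0 + np.exp(params.decay_rate * x))
    return out if out.ndim else float(out)


def _predict(kind, a, b, x):
    if kind == "edf":
        return b + np.exp(-a * x)
    return b + 1.0 / (1.0 + np.exp(a * x))


def fit_decay(swap_curve: MeanCurve, kind: str) -> DecayFit:
    """Least-squares fit of one decay law to a mean swap curve.

    Minimizes the mean squared error over (decay_rate, baseline) within
    the documented bounds, restarting from each initial decay rate in
    :data:`MULTISTART_RATES` to avoid local minima.
    """
    kind = _check_kind(kind)
    x, y = swap_curve.lags, swap_curve.values
    if x.size < 3:
        raise DataError("need at least 3 lag points to fit a decay law")

    best = None
    trace = []
    for a0 in MULTISTART_RATES:
        b0 = float(np.clip(y[-2:].mean(), *BASELINE_BOUNDS))
        try:
            res = optimize.least_squares(
                lambda th: _predict(kind, th[0], th[1], x) - y,
                np.array([a0, b0]),
                bounds=(
                    [DECAY_RATE_BOUNDS[0], BASELINE_BOUNDS[0]],
                    [DECAY_RATE_BOUNDS[1], BASELINE_BOUNDS[1]],
                ),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=10_000,
            )
        except Exception as exc:
            trace.append({"start": a0, "error": str(exc)})
            continue
        trace.append({"start": a0, "cost": res.cost, "success": res.success})
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(f"{kind.upper()} fit failed from all starts", trace=trace)
    a, b = best.x
    mse = float(2.0 * best.cost / x.size)
    return DecayFit(
        kind=kind,
        params=DecayParams(decay_rate=float(a), baseline=float(b)),
        mse=mse,
        lags_used=x,
    )


def compare_decay_models(group_swap_curves: Mapping[str, MeanCurve]) -> pd.DataFrame:
    """Fit both decay laws per group and pick the winner by smaller MSE.

    Returns one row per group and law with columns group, kind,
    decay_rate, baseline, mse, winner (bool).
    """
    rows = []
    for group, curve in group_swap_curves.items():
        fits = {kind: fit_decay(curve, kind) for kind in KINDS}
        winner = min(fits, key=lambda k: fits[k].mse)
        for kind, f in fits.items():
            rows.append(
                {
                    "group": group,
                    "kind": kind.upper(),
                    "decay_rate": f.params.decay_rate,
                    "baseline": f.params.baseline,
                    "mse": f.mse,
                    "winner": kind == winner,
                }
            )
    return pd.DataFrame(rows)


def subject_decay_rates(
    curves: Sequence[SubjectLagCurve], kind: str = "edf"
) -> tuple[dict[str, float], dict[str, str]]:
    """Per-subject decay-rate estimates from individual swap curves.

    Returns (rates, failures).  Subjects whose swap curve is identically
    zero carry no rate information and are reported in ``failures``
    instead of receiving an arbitrary estimate; fit failures are
    likewise per-subject, never fatal.
    """
    kind = _check_kind(kind)
    rates: dict[str, float] = {}
    failures: dict[str, str] = {}
    for c in curves:
        if np.all(c.pr_swap == 0):
            failures[c.subject_id] = "all-zero swap curve: decay rate unidentifiable"
            warnings.warn(
                f"subject {c.subject_id!r}: all-zero swap curve, rate not estimated"
            )
            continue
        try:
            fit = fit_decay(MeanCurve(c.lags, c.pr_swap), kind)
        except FitError as exc:
            failures[c.subject_id] = str(exc)
            continue
        rates[c.subject_id] = fit.params.decay_rate
    return rates, failures


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float


def correlate_decay_with_clinical(
    rates: Mapping[str, float],
    clinical: pd.DataFrame,
    variable: str,
) -> CorrelationResult:
    """Pearson correlation between decay rates and a clinical score.

    ``clinical`` must carry a ``subject_id`` column and the named score
    column.  df = n - 2 and the two-tailed p comes from the t transform
    t = r * sqrt(df / (1 - r^2)).
    """
    if "subject_id" not in clinical.columns:
        raise DataError("clinical table must have a subject_id column")
    if variable not in clinical.columns:
        raise DataError(f"clinical table has no column {variable!r}")
    merged = clinical.set_index("subject_id")[variable]
    pairs = [
        (rates[sid], merged[sid])
        for sid in rates
        if sid in merged.index and np.isfinite(merged[sid])
    ]
    if len(pairs) < 4:
        raise DataError("need at least 4 complete (rate, score) pairs")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined: zero variance in one variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), df=len(pairs) - 2, p=float(res.pvalue))
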