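"""Generative gamma model of attentional-blink accuracy curves.

The mean accuracy at lag ``x`` (TOA in 100 ms units) is modelled as an
inverted gamma density

    value(x) = c - d * gammapdf(x; a, b)

where ``a`` is the gamma shape, ``b`` the scale (in lag units), ``c`` the
baseline accuracy the curve recovers to at long lags, and ``d`` the depth
of the blink dip.  Simulated subjects add independent uniform noise
``e ~ U(-h, +h)`` at each lag, with half-width ``h = 0.4`` by default.

The module provides deterministic curve evaluation, noisy single-subject
and two-group cohort simulation, and nonlinear least-squares fitting with
an arbitrary subset of free parameters.  When only the baseline is free
the least-squares solution is the closed-form mean residual shift and no
iteration is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ParameterError
from .records import MeanCurve, as_lag_grid

__all__ = [
    "GammaABParams",
    "CONTROL_PARAMS",
    "PATIENT_BASELINE_OFFSET",
    "DEFAULT_LAGS",
    "ab_curve",
    "ab_curve_values",
    "simulate_subject_curve",
    "simulate_cohort",
    "Cohort",
    "fit_gamma_ab",
]

_PARAM_NAMES = ("shape", "scale", "baseline", "depth")


@dataclass(frozen=True)
class GammaABParams:
    """Parameter vector of the gamma blink-curve model."""

    shape: float
    scale: float
    baseline: float
    depth: float
    noise_halfwidth: float = 0.4

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ParameterError("shape and scale must be > 0")
        if not (0.0 <= self.baseline <= 1.0):
            raise ParameterError("baseline must lie in [0, 1]")
        if self.depth < 0:
            raise ParameterError("depth must be >= 0")
        if self.noise_halfwidth < 0:
            raise ParameterError("noise_halfwidth must be >= 0")

    def replace(self, **kwargs) -> "GammaABParams":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": self.shape,
                "scale": self.scale,
                "baseline": self.baseline,
                "depth": self.depth,
                "noise_halfwidth": self.noise_halfwidth,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GammaABParams":
        return cls(**json.loads(text))


#: Parameters fitted to a healthy-control group's mean blink curve, used
#: throughout as the canonical generating condition.
CONTROL_PARAMS = GammaABParams(shape=2.1, scale=0.96, baseline=0.86, depth=0.87)

#: Baseline decrement of the patient group relative to controls under the
#: baseline-shift-only null (equal blink depth by construction).
PATIENT_BASELINE_OFFSET = -0.16

#: Integer lag grid of the slow-presentation blink curve (lags 1..8).
DEFAULT_LAGS = np.arange(1.0, 9.0)


def ab_curve_values(params: GammaABParams, lags: Sequence[float]) -> np.ndarray:
    """Noise-free model curve as a bare array (unclipped)."""
    x = as_lag_grid(lags)
    g = stats.gamma.pdf(x, a=params.shape, scale=params.scale)
    return params.baseline - params.depth * g


def ab_curve(params: GammaABParams, lags: Sequence[float]) -> MeanCurve:
    """Deterministic expectation curve; values are returned unclipped so
    callers can detect parameterizations that leave [0, 1]."""
    lags = as_lag_grid(lags)
    return MeanCurve(lags, ab_curve_values(params, lags))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_subject_curve(
    params: GammaABParams,
    lags: Sequence[float],
    rng_seed,
    clip: bool = True,
) -> MeanCurve:
    """One subject's noisy curve: model value + U(-h, +h) per lag.

    ``clip=False`` keeps the raw (possibly out-of-[0,1]) values, which is
    what strict-null simulations need: clipping acts asymmetrically on
    groups with different baselines and would itself break the null.
    """
    lags = as_lag_grid(lags)
    rng = _rng(rng_seed)
    noise = rng.uniform(-params.noise_halfwidth, params.noise_halfwidth, size=lags.size)
    vals = ab_curve_values(params, lags) + noise
    if clip:
        vals = np.clip(vals, 0.0, 1.0)
    return MeanCurve(lags, vals)


@dataclass(frozen=True)
class Cohort:
    """Simulated two-group cohort of per-subject accuracy curves."""

    lags: np.ndarray
    groups: np.ndarray  # (n_subjects,) group labels
    values: np.ndarray  # (n_subjects, n_lags)

    def group_values(self, label: str) -> np.ndarray:
        return self.values[self.groups == label]


def simulate_cohort(
    control: GammaABParams,
    baseline_offset: float,
    n_per_group: int,
    lags: Sequence[float],
    rng_seed,
    clip: bool = True,
    labels: tuple = ("control", "patient"),
) -> Cohort:
    """Simulate two groups differing only by a baseline shift.

    The second group's parameters equal the first's with
    ``baseline + baseline_offset`` (negative offset = deficit); blink
    shape and depth are shared, so equal blink depth holds by
    construction.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    lags = as_lag_grid(lags)
    patient = control.replace(baseline=control.baseline + baseline_offset)  # validates
    rng = _rng(rng_seed)
    out = []
    for params in (control, patient):
        base = ab_curve_values(params, lags)
        noise = rng.uniform(
            -params.noise_halfwidth, params.noise_halfwidth, size=(n_per_group, lags.size)
        )
        vals = base[None, :] + noise
        if clip:
            vals = np.clip(vals, 0.0, 1.0)
        out.append(vals)
    groups = np.repeat(list(labels), n_per_group)
    return Cohort(lags=lags, groups=groups, values=np.vstack(out))


def fit_gamma_ab(
    curve: MeanCurve,
    free: Iterable[str] = _PARAM_NAMES,
    init: GammaABParams = CONTROL_PARAMS,
    ftol: float = 1e-10,
    max_nfev: int = 10_000,
) -> tuple[GammaABParams, float]:
    """Least-squares fit of the gamma blink model to a mean curve.

    Parameters named in ``free`` are estimated; the rest are held at
    ``init``.  Returns the fitted parameter set and the sum of squared
    errors.  ``free={'baseline'}`` uses the closed-form solution (the
    mean residual shift) and is independent of the baseline init.
    """
    free = tuple(free)
    unknown = set(free) - set(_PARAM_NAMES)
    if unknown:
        raise ParameterError(f"unknown free parameters: {sorted(unknown)}")
    if not free:
        raise ParameterError("at least one parameter must be free")
    x, y = curve.lags, curve.values
    if x.size < len(free) + 1:
        raise ParameterError(
            f"curve has {x.size} points; need at least {len(free) + 1}"
        )

    if set(free) == {"baseline"}:
        # value = c - d*g(x)  =>  c* = mean(y + d*g(x)), the OLS solution.
        g = stats.gamma.pdf(x, a=init.shape, scale=init.scale)
        c_hat = float(np.mean(y + init.depth * g))
        fitted = init.replace(baseline=min(max(c_hat, 0.0), 1.0))
        sse = float(np.sum((y - ab_curve_values(fitted, x)) ** 2))
        return fitted, sse

    if np.ptp(y) == 0 and {"shape", "scale"} & set(free):
        raise FitError(
            "constant curve: shape/scale are unidentifiable from a flat profile"
        )

    lower = {"shape": 1e-8, "scale": 1e-8, "baseline": 0.0, "depth": 0.0}
    upper = {"shape": np.inf, "scale": np.inf, "baseline": 1.0, "depth": np.inf}
    theta0 = np.array([getattr(init, name) for name in free])

    def residuals(theta):
        params = init.replace(**dict(zip(free, theta)))
        return ab_curve_values(params, x) - y

    result = optimize.least_squares(
        residuals,
        theta0,
        bounds=([lower[n] for n in free], [upper[n] for n in free]),
        method="trf",
        ftol=ftol,
        xtol=ftol,
        gtol=ftol,
        max_nfev=max_nfev,
    )
    if not result.success:
        raise FitError(
            f"gamma-model fit did not converge: {result.message}",
            trace=[{"status": result.status, "nfev": result.nfev, "cost": result.cost}],
        )
    fitted = init.replace(**dict(zip(free, result.x)))
    sse = float(2.0 * result.cost)
    return fitted, sse
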