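import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blinkstat as bs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the infeasible-swap-rate warning is an expected byproduct of the noisy
# generative defaults; keep test output readable
logging.getLogger("blinkstat.simulate").setLevel(logging.ERROR)


@pytest.fixture
def lags8() -> np.ndarray:
    """Integer lag grid 1..8 of the slow-presentation blink curve."""
    return np.arange(1.0, 9.0)


@pytest.fixture
def control_params() -> bs.GammaABParams:
    return bs.CONTROL_PARAMS


def make_curves(groups, Y, lags, measure="pr_t2_given_t1"):
    """Wrap a subjects-by-lags matrix into SubjectLagCurve records."""
    curves = []
    for i, (g, row) in enumerate(zip(groups, Y)):
        kw = {
            "pr_t1": np.ones_like(row),
            "pr_t2_given_t1": np.zeros_like(row),
            "pr_swap": np.zeros_like(row),
        }
        kw[measure] = row
        if measure != "pr_t1" and np.any(row > 1):
            kw["pr_t1"] = np.maximum(kw["pr_t1"], row)
        curves.append(
            bs.SubjectLagCurve(subject_id=f"s{i:03d}", group=str(g), lags=lags, **kw)
        )
    return curves
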