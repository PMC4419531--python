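"""Study configuration: schema-validated JSON config and the two presets.

A study config either names a preset (``exp1`` — patients vs controls
with per-group SOAs of 100 vs 50 ms, TOAs 100–1200 ms, 24 subjects per
group; ``exp2`` — SPD vs non-SPD, both at 50 ms SOA, TOAs 50–600 ms,
25 per group) or spells out the protocol and per-group generative
parameters in full.  Unknown keys are rejected.  The JSON schema is
shipped in the package data (``data/study_config.schema.json``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

__all__ = [
    "ProtocolSpec",
    "CurveSpec",
    "SwapSpec",
    "GroupSpec",
    "AnalysisFlags",
    "StudyConfig",
    "load_config",
    "config_hash",
    "EXP1",
    "EXP2",
]

TARGET_POOL = list("23456789")  # eight digits
DISTRACTOR_POOL = list("ACEFHJKLMNPRTUVX")  # sixteen capital letters


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSpec(_Strict):
    """Presentation protocol shared by every subject of a study."""

    toas_ms: list[int] = Field(min_length=1)
    soa_by_group: dict[str, int]
    dual_target_fraction: float = Field(0.75, gt=0.0, le=1.0)
    #: total trials per TOA per subject; with the default dual-target
    #: fraction of 3/4 this yields 30 dual-target trials per TOA.
    trials_per_toa: int = Field(40, ge=1)
    target_pool: list[str] = Field(default_factory=lambda: list(TARGET_POOL))
    distractor_pool: list[str] = Field(default_factory=lambda: list(DISTRACTOR_POOL))

    @model_validator(mode="after")
    def _check(self):
        if sorted(self.toas_ms) != self.toas_ms or len(set(self.toas_ms)) != len(
            self.toas_ms
        ):
            raise ValueError("toas_ms must be strictly increasing")
        for group, soa in self.soa_by_group.items():
            if soa <= 0:
                raise ValueError(f"SOA for group {group!r} must be positive")
            bad = [t for t in self.toas_ms if t % soa != 0]
            if bad:
                raise ValueError(
                    f"TOAs {bad} are not divisible by group {group!r} SOA {soa}"
                )
        if set(self.target_pool) & set(self.distractor_pool):
            raise ValueError("target and distractor pools must be disjoint")
        if len(self.target_pool) < 3:
            raise ValueError("need at least 3 targets (triple-target trials)")
        return self

    @property
    def lags(self) -> list[float]:
        return [t / 100.0 for t in self.toas_ms]


class CurveSpec(_Strict):
    """Gamma blink-curve parameters of one generative accuracy curve."""

    shape: float = Field(gt=0)
    scale: float = Field(gt=0)
    baseline: float = Field(ge=0, le=1)
    depth: float = Field(ge=0)
    noise_halfwidth: float = Field(0.4, ge=0)


class SwapSpec(_Strict):
    """Decay-law parameters of the generative swap-probability curve."""

    kind: Literal["ldf", "edf"]
    decay_rate: float = Field(gt=0)
    baseline: float = Field(ge=0, lt=1)
    noise_halfwidth: float = Field(0.02, ge=0)


class GroupSpec(_Strict):
    t1_curve: CurveSpec
    t2_curve: CurveSpec
    swap: SwapSpec


class AnalysisFlags(_Strict):
    sr_form: Literal["deficit", "ratio"] = "deficit"
    baseline_mode: Literal["subject", "group"] = "subject"
    scoring: Literal["position_free", "strict"] = "position_free"
    bf_method: Literal["bic", "prior-integration"] = "bic"
    alpha: float = Field(0.05, gt=0, lt=1)
    holm: bool = False


class StudyConfig(_Strict):
    preset: Optional[Literal["exp1", "exp2"]] = None
    protocol: Optional[ProtocolSpec] = None
    groups: Optional[dict[str, GroupSpec]] = None
    n_per_group: Optional[int] = Field(None, ge=1)
    analysis: AnalysisFlags = Field(default_factory=AnalysisFlags)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self):
        if self.preset is None and (self.protocol is None or self.groups is None):
            raise ValueError("either a preset or a full protocol+groups is required")
        return self

    def resolved(self) -> "StudyConfig":
        """Fill preset fields in, leaving explicit overrides untouched."""
        if self.preset is None:
            return self
        base = {"exp1": EXP1, "exp2": EXP2}[self.preset]
        merged = base.model_dump()
        own = self.model_dump(exclude_none=True, exclude={"preset"})
        merged.update(own)
        merged["preset"] = self.preset
        return StudyConfig(**merged)


# Shared generative accuracy curves: groups are baseline-matched by the
# presentation-rate manipulation, so both groups draw from the same
# first-target and conditional second-target curves.  The second-target
# curve is the canonical fitted blink curve; the first-target curve
# shares its shape with a shallower dip.
_T1_CURVE = CurveSpec(shape=2.1, scale=0.96, baseline=0.86, depth=0.35)
_T2_CURVE = CurveSpec(shape=2.1, scale=0.96, baseline=0.86, depth=0.87)

EXP1 = StudyConfig(
    preset="exp1",
    protocol=ProtocolSpec(
        toas_ms=[100, 200, 300, 400, 600, 800, 1200],
        soa_by_group={"patient": 100, "control": 50},
    ),
    groups={
        # decay parameters follow the published group-level fits:
        # exponential decay for patients, logistic for controls
        "patient": GroupSpec(
            t1_curve=_T1_CURVE,
            t2_curve=_T2_CURVE,
            swap=SwapSpec(kind="edf", decay_rate=1.3, baseline=0.03),
        ),
        "control": GroupSpec(
            t1_curve=_T1_CURVE,
            t2_curve=_T2_CURVE,
            swap=SwapSpec(kind="ldf", decay_rate=1.4, baseline=0.06),
        ),
    },
    n_per_group=24,
)

EXP2 = StudyConfig(
    preset="exp2",
    protocol=ProtocolSpec(
        toas_ms=[50, 100, 150, 200, 300, 400, 600],
        soa_by_group={"spd": 50, "non_spd": 50},
    ),
    groups={
        "spd": GroupSpec(
            t1_curve=_T1_CURVE,
            t2_curve=_T2_CURVE,
            swap=SwapSpec(kind="ldf", decay_rate=1.4, baseline=0.06),
        ),
        "non_spd": GroupSpec(
            t1_curve=_T1_CURVE,
            t2_curve=_T2_CURVE,
            swap=SwapSpec(kind="ldf", decay_rate=1.4, baseline=0.04),
        ),
    },
    n_per_group=25,
)


def load_config(source) -> StudyConfig:
    """Load a study config from a dict, JSON string/path, or preset name."""
    try:
        if isinstance(source, StudyConfig):
            return source.resolved()
        if isinstance(source, dict):
            return StudyConfig(**source).resolved()
        if isinstance(source, (str, Path)):
            text = str(source)
            if text in ("exp1", "exp2"):
                return StudyConfig(preset=text).resolved()
            path = Path(source)
            if path.exists():
                return StudyConfig(**json.loads(path.read_text())).resolved()
            return StudyConfig(**json.loads(text)).resolved()
    except (pydantic.ValidationError, json.JSONDecodeError, ValueError) as exc:
        raise ConfigError(f"invalid study config: {exc}") from exc
    raise ConfigError(f"cannot interpret config source of type {type(source)!r}")


def config_hash(config: StudyConfig) -> str:
    """Stable sha256 over the canonical JSON form of a config."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
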