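"""Trial-level synthetic RSVP data generator.

Builds complete synthetic studies with no human data: each subject gets
a "true" per-lag response profile (accuracy curves from the gamma blink
model, swap probabilities from a decay law, all with per-lag subject
noise), and trial records are then sampled from those probabilities.

Response model per dual-target trial at TOA tau: T1 is reported with
pr_t1(tau); conditional on T1, T2 is reported with pr_t2_given_t1(tau);
when both are reported the order is reversed with probability
pr_swap / (pr_t1 * pr_t2_given_t1), capped at 1, so the marginal swap
rate matches the truth wherever feasible.  One quarter of trials carry a
third target 800 ms after T2; they keep attention on the stream in the
real protocol and are flagged for exclusion from every analysis here.

Seeding: each subject's random stream is derived from
``SeedSequence([master_seed, group_index, subject_index])``, so adding
subjects or groups never perturbs the data of existing ones.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import GroupSpec, ProtocolSpec, StudyConfig, config_hash, load_config
from .decay import DecayParams, decay_value
from .errors import ConfigError, DataError
from .model import GammaABParams, ab_curve_values
from .records import (
    TRIAL_CSV_COLUMNS,
    TRUTH_CSV_COLUMNS,
    SubjectLagCurve,
    TrialRecord,
    as_lag_grid,
)

__all__ = [
    "generate_subject_truth",
    "generate_trials",
    "build_study",
    "trials_to_frame",
    "truth_to_frame",
    "read_trials_csv",
]

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _curve_params(spec) -> GammaABParams:
    if isinstance(spec, GammaABParams):
        return spec
    return GammaABParams(
        shape=spec.shape,
        scale=spec.scale,
        baseline=spec.baseline,
        depth=spec.depth,
        noise_halfwidth=spec.noise_halfwidth,
    )


def generate_subject_truth(
    group_params: GroupSpec,
    lags: Sequence[float],
    seed,
    subject_id: str = "s000",
    group: str = "group",
) -> SubjectLagCurve:
    """Draw one subject's true per-lag response profile.

    Accuracy curves are the gamma blink model plus per-lag uniform
    noise, clipped to [0, 1]; swap probabilities are the group's decay
    law plus per-lag uniform subject noise, clipped to [0, 1] and then
    to the structural constraint pr_swap <= pr_t1.
    """
    lags = as_lag_grid(lags)
    rng = _rng(seed)
    t1p = _curve_params(group_params.t1_curve)
    t2p = _curve_params(group_params.t2_curve)
    pr_t1 = np.clip(
        ab_curve_values(t1p, lags)
        + rng.uniform(-t1p.noise_halfwidth, t1p.noise_halfwidth, lags.size),
        0.0,
        1.0,
    )
    pr_t2 = np.clip(
        ab_curve_values(t2p, lags)
        + rng.uniform(-t2p.noise_halfwidth, t2p.noise_halfwidth, lags.size),
        0.0,
        1.0,
    )
    swap_spec = group_params.swap
    base_swap = decay_value(
        swap_spec.kind,
        DecayParams(decay_rate=swap_spec.decay_rate, baseline=swap_spec.baseline),
        lags,
    )
    pr_swap = np.clip(
        base_swap
        + rng.uniform(-swap_spec.noise_halfwidth, swap_spec.noise_halfwidth, lags.size),
        0.0,
        1.0,
    )
    pr_swap = np.minimum(pr_swap, pr_t1)
    return SubjectLagCurve(
        subject_id=subject_id,
        group=group,
        lags=lags,
        pr_t1=pr_t1,
        pr_t2_given_t1=pr_t2,
        pr_swap=pr_swap,
    )


def generate_trials(
    truth: SubjectLagCurve,
    protocol: ProtocolSpec,
    seed,
) -> list[TrialRecord]:
    """Sample a subject's trial records from their truth profile."""
    rng = _rng(seed)
    if truth.group not in protocol.soa_by_group:
        raise ConfigError(f"protocol defines no SOA for group {truth.group!r}")
    toas = np.asarray(protocol.toas_ms)
    lags = toas / 100.0
    if lags.shape != truth.lags.shape or not np.allclose(lags, truth.lags):
        raise DataError("truth lag grid does not match the protocol TOA grid")

    targets = list(protocol.target_pool)
    capped = False
    toa_idx = np.repeat(np.arange(toas.size), protocol.trials_per_toa)
    n_total = toa_idx.size
    dual_flags = rng.random(n_total) < protocol.dual_target_fraction
    order = rng.permutation(n_total)

    # conditional swap probability, capped at 1 where the marginal swap
    # rate exceeds the probability of reporting both targets
    p_both = truth.pr_t1 * truth.pr_t2_given_t1
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_swap = np.where(p_both > 0, truth.pr_swap / p_both, 0.0)
    if np.any(cond_swap > 1.0):
        capped = True
        cond_swap = np.minimum(cond_swap, 1.0)

    # bulk randomness: target identities (3 distinct per trial) + outcome draws
    ids = np.argsort(rng.random((n_total, len(targets))), axis=1)[:, :3]
    u1, u2, usw, u3 = rng.random((4, n_total))
    # long-lag first-target accuracy stands in for single-target accuracy
    pr_t3 = float(truth.pr_t1[-1])

    trials = []
    for trial_index, pos in enumerate(order):
        i = toa_idx[pos]
        dual = bool(dual_flags[pos])
        t1 = targets[ids[pos, 0]]
        t2 = targets[ids[pos, 1]]
        t3 = "" if dual else targets[ids[pos, 2]]

        report: list[str] = []
        t1_ok = u1[pos] < truth.pr_t1[i]
        t2_ok = t1_ok and u2[pos] < truth.pr_t2_given_t1[i]
        if t1_ok and t2_ok:
            report = [t2, t1] if usw[pos] < cond_swap[i] else [t1, t2]
        elif t1_ok:
            report = [t1]
        if not dual and u3[pos] < pr_t3:
            report.append(t3)

        trials.append(
            TrialRecord(
                subject_id=truth.subject_id,
                group=truth.group,
                trial_index=trial_index,
                condition="dual" if dual else "triple",
                toa_ms=int(toas[i]),
                t1=t1,
                t2=t2,
                t3=t3,
                reported=tuple(report),
            )
        )
    if capped:
        logger.warning(
            "subject %s: swap rate exceeded Pr(both reported) at some lag; "
            "conditional swap probability capped at 1",
            truth.subject_id,
        )
    return trials


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rep = list(t.reported) + [""] * (3 - len(t.reported))
        rows.append(
            (
                t.subject_id,
                t.group,
                t.trial_index,
                t.condition,
                t.toa_ms,
                t.t1,
                t.t2,
                t.t3,
                rep[0],
                rep[1],
                rep[2],
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def truth_to_frame(truths: Sequence[SubjectLagCurve]) -> pd.DataFrame:
    rows = []
    for tr in truths:
        for j in range(tr.lags.size):
            rows.append(
                (
                    tr.subject_id,
                    tr.group,
                    tr.lags[j],
                    tr.pr_t1[j],
                    tr.pr_t2_given_t1[j],
                    tr.pr_swap[j],
                )
            )
    return pd.DataFrame(rows, columns=TRUTH_CSV_COLUMNS)


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial CSV, validating the documented header."""
    df = pd.read_csv(path, dtype={"t1": str, "t2": str, "t3": str,
                                  "report_1": str, "report_2": str,
                                  "report_3": str},
                     keep_default_na=False)
    for got, want in zip(df.columns, TRIAL_CSV_COLUMNS):
        if got != want:
            raise DataError(
                f"trial CSV header must be {TRIAL_CSV_COLUMNS}; "
                f"first bad column: {got!r}"
            )
    if len(df.columns) != len(TRIAL_CSV_COLUMNS):
        raise DataError(f"trial CSV header must be exactly {TRIAL_CSV_COLUMNS}")
    return df


def build_study(
    config,
    seed: int,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study (all groups, all subjects).

    Returns (trials, truth) data frames; when ``out_dir`` is given they
    are also written as ``trials.csv`` and ``truth.csv`` along with a
    ``manifest.json`` recording the seed, config hash and version.
    Identical (config, seed) pairs produce byte-identical files.
    """
    cfg: StudyConfig = load_config(config)
    protocol = cfg.protocol
    groups = cfg.groups
    n_per_group = cfg.n_per_group or 24
    lags = protocol.lags

    all_truths: list[SubjectLagCurve] = []
    all_trials: list[TrialRecord] = []
    for gi, (group, gspec) in enumerate(sorted(groups.items())):
        for si in range(n_per_group):
            sid = f"{group}_{si:03d}"
            truth_rng = np.random.default_rng(
                np.random.SeedSequence([seed, gi, si, 0])
            )
            trial_rng = np.random.default_rng(
                np.random.SeedSequence([seed, gi, si, 1])
            )
            truth = generate_subject_truth(
                gspec, lags, truth_rng, subject_id=sid, group=group
            )
            all_truths.append(truth)
            all_trials.extend(generate_trials(truth, protocol, trial_rng))

    trials_df = trials_to_frame(all_trials)
    truth_df = truth_to_frame(all_truths)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials_df.to_csv(out / "trials.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False, float_format="%.10g")
        manifest = {
            "seed": seed,
            "config_hash": config_hash(cfg),
            "preset": cfg.preset,
            "n_subjects": len(all_truths),
            "n_trials": len(all_trials),
            "blinkstat_version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return trials_df, truth_df
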