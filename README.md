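# blinkstat

Simulation and analysis toolkit for dual-target RSVP (rapid serial
visual presentation) studies of the attentional blink (AB), written for
researchers comparing AB performance between clinical groups — e.g.
schizophrenia patients vs healthy controls — where the groups differ in
baseline perceptual accuracy.

The package addresses a specific methodological trap. A common way to
"correct" for baseline differences is the per-lag suppression ratio

    SR(x) = [Pr(T1) − Pr(T2|T1)] / Pr(T1)

with Pr(T1) the baseline single-target accuracy (estimated as the mean
of the last two lags). Because this transform is nonlinear in the
baseline, a fixed raw group difference maps to a *larger* SR difference
at low-performance lags (inside the blink) than at high-performance
lags — so two groups that differ only by a baseline shift acquire a
spurious group × lag interaction after the transform. `blinkstat` makes
that argument quantitative with a Monte-Carlo study, and provides every
surrounding piece: a generative model of blink curves, a trial-level
synthetic data generator, the standard group analyses, and decay-law
modelling of temporal order errors.

## What's inside

- **`blinkstat.model`** — generative gamma model of AB accuracy curves:
  value(x) = c − d·γ(x; a, b), with γ the gamma density over lag
  x = TOA/100 ms; shape a, scale b, baseline c, blink depth d; per-lag
  subject noise e ~ U(−0.4, 0.4). Curve evaluation, cohort simulation,
  and nonlinear least-squares fitting (full or baseline-only refit).
- **`blinkstat.suppression`** — the SR transform and
  `run_artifact_study` / `replicate_artifact_power`: simulate a pure
  baseline-shift null, analyse raw and SR-transformed curves with the
  same mixed ANOVA, and estimate rejection rates with exact binomial
  confidence intervals.
- **`blinkstat.simulate`** — trial-level synthetic studies: two
  presets (patients at 100 ms SOA vs controls at 50 ms, TOAs
  100–1200 ms; SPD vs non-SPD both at 50 ms, TOAs 50–600 ms), 3/4
  dual-target trials plus 1/4 triple-target catch trials flagged for
  exclusion, reports sampled from per-subject truth profiles.
- **`blinkstat.analysis`** — trial aggregation to per-subject curves
  (Pr(T1), Pr(T2|T1), swap rate), classical two-way mixed ANOVA
  (group × lag, no sphericity correction), per-lag simple effects,
  baseline-match t test, and a Bayes factor for the interaction
  (BIC-based, or g-prior marginal likelihoods with inverse-gamma(0.5,
  0.25)/(0.5, 0.5) priors integrated by quadrature).
- **`blinkstat.decay`** — logistic vs exponential decay laws for swap
  curves, LDF(x) = b + 1/(1+e^{ax}) and EDF(x) = b + e^{−ax}; MSE-based
  model selection, per-subject decay rates, and Pearson correlation
  with clinical scores.
- **`blinkstat.summary_tables`** — pooled-variance t tests recomputed
  from printed mean (SD) group summaries, with the two demographic
  reference tables shipped as CSV.

## Worked example

Simulate the baseline-shift null (control parameters a=2.1, b=0.96,
c=0.86, d=0.87; patient baseline 0.16 lower; 100 subjects per group,
lags 1–8) and compare raw vs suppression-ratio analyses over 200
replicates:

```python
import numpy as np
import blinkstat as bs
from blinkstat.suppression import replicate_artifact_power

power = replicate_artifact_power(
    bs.CONTROL_PARAMS, -0.16, 100, np.arange(1, 9),
    n_replicates=200, seed=7,
)
print(power.table)
```

```
            effect  rejections    n   rate    ci_low   ci_high
0        raw_group         200  200  1.000  0.973856  1.000000
1          raw_lag         200  200  1.000  0.973856  1.000000
2  raw_interaction           7  200  0.035  0.010289  0.083516
3         sr_group          14  200  0.070  0.031697  0.129894
4           sr_lag         200  200  1.000  0.973856  1.000000
5   sr_interaction          48  200  0.240  0.166745  0.326004
```

Read: on the raw curves the baseline shift shows up as it should — the
group and lag main effects always reject, and the group × lag
interaction stays at the nominal 5% level (3.5%, true null). After the
suppression-ratio transform the *same data* reject the interaction null
24% of the time, almost five times the nominal rate: the normalization
manufactures an apparent group difference in blink shape that is not in
the data.

The baseline-only refit illustrates the generating null itself:

```python
curve = bs.ab_curve(bs.CONTROL_PARAMS, np.arange(1, 9))
shifted = bs.MeanCurve(curve.lags, curve.values - 0.16)
params, sse = bs.fit_gamma_ab(shifted, free={"baseline"})
print(params.baseline)   # 0.7
```

The same operations are available from the shell:

```bash
blinkstat simulate --preset exp1 --seed 1 --out study/
blinkstat analyze --trials study/trials.csv --measure t2_given_t1 \
    --bf bic --out anova.json
blinkstat sr-audit --replicates 200 --seed 7 --out audit.json
blinkstat fit-decay --curves swaps.csv --kind both --out decay.json
blinkstat summary-t --summaries table.csv --out t.csv
```

Exit codes: 0 success, 2 configuration error, 3 data error. Every run
writes a manifest (seed, config hash, version) next to its output.

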