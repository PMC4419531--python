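# Methods

This note documents the models implemented in `blinkstat`, the
assumptions behind them, the defaults and why they were chosen, and the
numerical decisions a maintainer would want to know. Every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## The gamma blink-curve model

Mean report accuracy as a function of lag x (target onset asynchrony in
units of 100 ms) is modelled as an inverted gamma density,

    value(x) = c − d · γ(x; a, b),   γ(x; a, b) = x^{a−1} e^{−x/b} / (Γ(a) b^a),

with shape a > 0, scale b > 0 (lag units), baseline c ∈ [0, 1] and
blink depth d ≥ 0. The curve dips to its minimum at the gamma mode
x = (a−1)b and recovers to c at long lags. The canonical control
parameterization used throughout is (a, b, c, d) = (2.1, 0.96, 0.86,
0.87), giving a dip to ≈ 0.54 near lag 1 and a baseline of 0.86; a
patient group under the *baseline-shift null* uses the same (a, b, d)
with c lowered by 0.16 to 0.70. A baseline-only refit of the shifted
curve is a linear least-squares problem and is solved in closed form
(the mean residual shift); it recovers c = 0.70 exactly.

Simulated subjects add independent per-lag noise e ~ U(−h, +h) with
half-width h = 0.4 by default. Two things follow from the size of that
noise and matter below:

- the per-observation SD is h/√3 ≈ 0.231, comparable to the blink depth
  itself, so single-dataset inferences are noisy;
- with c = 0.86, unclipped values can exceed 1. Clipping to [0, 1] is
  applied by default when simulating *subjects* (they are probabilities)
  but **disabled by default in the artifact study**, because clipping
  truncates the higher-baseline group more than the lower one and would
  by itself create a real group × lag interaction, destroying the null
  the study is designed to hold. A flag restores clipping.

Full fits use trust-region bounded least squares (`scipy.optimize
.least_squares`, ftol = xtol = gtol = 1e−10, ≤ 10,000 evaluations),
with the control estimates as default initial values. Noise-free
recovery over 50 random parameter draws (shape ∈ [1.5, 3], scale ∈
[0.5, 1.5], baseline ∈ [0.7, 0.95], depth ∈ [0.4, 1]) is accurate to
< 1e−3 in every parameter (measured max error ≈ 5e−8). A constant
curve leaves shape and scale unidentifiable and raises a diagnostic
error rather than returning an arbitrary answer.

## The suppression-ratio artifact

The suppression ratio normalizes conditional T2 accuracy by the
subject's baseline Pr(T1), estimated as the mean of the last two lags:
SR = (Pr(T1) − Pr(T2|T1)) / Pr(T1) (deficit form; the plain ratio
Pr(T2|T1)/Pr(T1) is available behind a switch and, being an affine
complement per observation, yields identical ANOVA F statistics). The
transform is applied per subject by default; a per-group-mean-baseline
variant is available.

Mechanism: for two groups with baselines c₁ > c₂ and a *shared* blink
profile s(x), the expected SR group difference is approximately
−s(x)·(1/c₂ − 1/c₁) — proportional to the blink depth at each lag, i.e.
a pure group × lag interaction, even though the raw difference is a
constant shift. At the default parameters the induced SR gap is ≈ 0.085
at the dip and ≈ 0 at the last lags.

The artifact study simulates 100 subjects per group on lags 1–8 under
the baseline-shift null and runs the identical mixed ANOVA on raw and
SR-transformed curves. Across 200 replicates (the default study size;
~3 s on one CPU):

- raw interaction rejection at α = 0.05: ~0.035–0.065 (inside the exact
  binomial 99% interval around the nominal level — the raw null is
  clean);
- SR interaction rejection: ~0.24–0.28, a five- to seven-fold
  inflation with non-overlapping 99% confidence intervals;
- raw group and lag main effects reject always; the SR group main
  effect rejects at ~0.07–0.10.

A caveat the package reports honestly: the *joint* qualitative pattern
(raw: group + lag significant, interaction not; SR: lag significant,
group not, interaction significant) holds in only ~19% of replicates,
because the per-replicate power of the SR-induced interaction is
limited. This is inherent to the stated noise level, not an
implementation artifact: the interaction noncentrality implied by the
±0.085 deviation profile against a within-cell SD of ≈ 0.30 (noise
0.231 divided by baselines ≈ 0.78) is λ ≈ 4, giving ≈ 25% power for
F(7, 1386); the ANOVA core also matches `pingouin.mixed_anova` to
machine precision on the same data. A single simulated experiment can
therefore exhibit the full published pattern, but a typical one shows
the inflation without per-dataset significance. The replication-level
quantities (nominal raw rate, inflated SR rate) are the reproducible
substance.

## Synthetic trial-level studies

The generator emulates the two empirical protocols: `exp1` (24
patients at 100 ms SOA vs 24 controls at 50 ms; TOAs 100, 200, 300,
400, 600, 800, 1200 ms) and `exp2` (25 SPD vs 25 non-SPD, both 50 ms
SOA; TOAs 50–600 ms). Targets are 8 digits; 16 capital letters serve as
distractors. Three-quarters of trials carry two targets; the rest carry
a third target 800 ms after T2 and are flagged for exclusion from every
analysis (their role in the real task is to hold attention late in the
stream). The trial count per TOA is not part of the published designs;
the default is 40 total (≈ 30 dual-target) per TOA per subject,
configurable.

Per subject, a truth profile is drawn first: Pr(T1) and Pr(T2|T1)
curves from the gamma model plus uniform per-lag noise (clipped to
[0, 1]), and a swap-probability curve from the group's decay law plus
uniform noise (half-width 0.02 by default) clipped to [0, 1] and to the
structural constraint pr_swap ≤ pr_t1. The two groups share their
accuracy curves in both presets — the presentation-rate manipulation is
assumed to have matched baselines — and differ only in the swap decay
law (patients: exponential, rate 1.3, baseline 0.03; the other groups:
logistic, rate 1.4, baselines 0.04–0.06, following the published
group-level fits). Trials are then Bernoulli draws: T1 reported with
pr_t1; T2 conditional on T1 with pr_t2_given_t1; given both, the order
is reversed with probability pr_swap/(pr_t1·pr_t2_given_t1), capped at
1 (and logged) where the marginal swap rate is infeasible.

Seeding: subject i of group g uses
`SeedSequence([master_seed, g, i, {0: truth, 1: trials}])`, so adding
subjects or groups never perturbs existing data, and identical
(config, seed) pairs produce byte-identical CSVs.

What the generator does *not* emulate: distractor intrusions and
position-specific report errors (reports are correct/absent/swapped
outcomes only), any empirical coupling between blink depth and swap
rate, stimulus-level factors (identity confusability, serial position)
and the adaptive SOA titration (only its outcome, the SOA values, is
used). Passing tests on these data therefore validate the analysis
pipeline's arithmetic and contracts, not the behavioural realism of any
particular effect size.

A round-trip check ties generator and aggregator together: at 50,000
trials per TOA the aggregated curves deviate from the truth profile by
< 0.01 everywhere (measured ≈ 0.006).

## Group analysis

Aggregation scores a dual trial position-free by default (T1 counts as
reported wherever it appears; a swap is both targets reported in
reversed order); a strict-position rule is available. A subject × TOA
cell with no dual trials raises an error naming the cell — no
imputation.

The mixed ANOVA is the classical univariate partition for one
between-subject factor (group) and one within-subject factor (lag),
computed directly on the wide subjects × lags matrix: F_group =
MS_group/MS_subjects-within-groups, F_lag and F_interaction against
MS_within-error; no sphericity correction by default, matching the
degrees of freedom convention (1, n−2) and (k−1, (n−2)(k−1)). A
Greenhouse–Geisser option is available behind a flag (epsilon from the
pooled within-group covariance; the p values of the within-subject
effects are evaluated at epsilon-scaled dfs while the reported integer
dfs stay uncorrected). Zero-variance error
terms yield F = 0, p = 1 by convention so deterministic toy fixtures
run. The implementation is cross-checked in the tests against a
longhand 2×2×2 sums-of-squares derivation and against
`pingouin.mixed_anova` (agreement to machine precision); it exists as
its own numpy routine because the Monte-Carlo loops call it hundreds of
times and the long-format path of the library implementation is ~250×
slower per call.

Simple effects are independent two-sample pooled-variance t tests per
lag (a paired test is impossible between unmatched groups), two-tailed,
uncorrected by default with Holm correction behind a flag. The same
pooled t (sign convention: second group minus first) underlies the
baseline-match test and the summary-table reproductions.

### Interaction Bayes factor

Both methods compare the model with the group × lag interaction to the
one without it; both models keep the main effects and subject random
intercepts.

- **BIC method (default).** Both mixed models are fitted by maximum
  likelihood and BF₁₀ = exp((BIC_null − BIC_alt)/2). For a balanced
  complete design the random-intercept ML likelihood has an exact
  closed form via the between/within decomposition (the compound
  symmetric covariance has eigenvalues σ² + kτ² on subject means and σ²
  on within-subject contrasts), including the τ² = 0 boundary, where
  generic iterative fitters fail; the closed form matches
  `statsmodels` MixedLM to ~1e−4 log-likelihood units on non-degenerate
  data.
- **Prior-integration method (reference).** Sum-to-zero orthonormal
  contrasts code the fixed effects; each effect block's coefficients
  get a N(0, g σ² I) prior with g ~ InverseGamma(0.5, 0.25) for fixed
  blocks and InverseGamma(0.5, 0.5) for the subject block; the error
  variance has the Jeffreys prior 1/σ². Integrating coefficients, grand
  mean and σ² analytically leaves a low-dimensional integral over the g
  parameters, evaluated by Gauss–Legendre quadrature (12 nodes per
  dimension by default) after mapping each axis through the prior
  inverse CDF; the linear algebra runs through the Woodbury identity on
  the p × p inner matrix, batched over the quadrature grid. On a 2×2
  toy the quadrature marginal likelihood matches brute-force Monte
  Carlo integration with 10⁶ prior draws to ≈ 0.05% (tolerance 2%).

On synthetic null studies (shared accuracy curves) both methods give
BF₁₀ well below 1/3, and the two methods agree in direction on ≥ 90% of
simulated datasets; the BIC route is the default because it is
essentially free, the prior-integration route is the reference for what
the stated priors imply.

## Decay laws for temporal order errors

Swap probability by lag is fitted with two two-parameter laws,
EDF(x) = b + e^{−ax} and LDF(x) = b + 1/(1 + e^{ax}) (anchors b+1 and
b+0.5 at x = 0; both → b as x → ∞). Fits minimize MSE by bounded least
squares with a ∈ (0, 10], b ∈ [0, 0.5] (swap baselines above 0.5 are
behaviorally meaningless) and multistart over initial rates {0.5, 1,
1.5, 2, 3}. Model selection is by raw MSE — both laws have two
parameters, so no complexity correction applies. Group-level fits use
the across-subject mean swap curve; per-subject exponential rates feed
the clinical correlation (Pearson, df = n−2), with all-zero swap curves
reported as missing rather than fitted.

Noise-free curves generated from the published group fits (patient EDF
1.3/0.03; control and SPD LDF 1.4/0.06; non-SPD LDF 1.4/0.04) are
recovered to < 1e−4 and the winning family always matches the
generating one. An important measured limitation: **the two families
mimic each other closely** — an exponential can shadow a logistic curve
of these parameters to within ≈ 4e−5 MSE on the seven-lag grid. Model
selection is therefore only reliable when observation noise is below
that floor. Measured selection accuracy for LDF-generated curves (200
replicates × 3 seeds): σ = 0.01 → ≈ 79%; σ = 0.005 → 92–95%;
σ = 0.0025 → 100%. The consistency tests and the acceptance report use
σ = 0.0025; with ~30 dual trials per TOA per subject, *group-mean*
curves from ≈ 25 subjects reach this noise level, individual-subject
curves do not — which is why qualitative (which-family) claims belong at
the group level, and per-subject analysis uses the EDF rate as a
continuous index instead. Rate recovery from trial-level data reaches
r > 0.9 against generating rates with ≈ 300 dual trials per TOA.

## Summary-table t tests

Group rows printed as mean (SD) with group sizes are compared with the
pooled-variance Student t, t = (m₂ − m₁)/(s_p √(1/n₁ + 1/n₂)), df =
n₁ + n₂ − 2, which reproduces 17 of the 20 testable rows of the two
shipped demographic tables to 2 decimal places. Three rows of the
N-back block (0-back RT, 1-back ACC, 2-back ACC) do not follow from
their own printed summaries under either the pooled or Welch formula
(implied values −2.15, 2.78, 3.19 vs printed −2.05, 2.59, 2.98); they
are marked as known source discrepancies rather than forced to agree.
p values render to 3 significant figures with "<0.001" below that.

## Problem sizes and runtimes

Defaults were chosen so the full test suite runs in about a minute and
the acceptance script in ≈ 15 s on one CPU: 200 replicates for the
artifact study and for each model-selection direction, 400 replicates
for type-I-error calibration checks at smaller n, 50 draws for
parameter recovery, one subject at 50,000 trials/TOA for the round
trip, and the 24+24-subject preset for the end-to-end study analysis.
All stochastic computations derive their streams from explicit seeds
(`numpy.random.SeedSequence` spawning) and are exactly reproducible.

## Known limitations

- The artifact study's per-replicate power point above: under the
  stated noise the published joint significance pattern is a plausible
  single draw, not the modal outcome.
- The Bayes factor uses random intercepts only (no random slopes), and
  the balanced-design closed form is exact only for complete designs —
  incomplete designs raise an error rather than silently approximating.
- The generator's groups share accuracy curves by design; it cannot be
  used off-the-shelf to study accuracy-difference questions without
  overriding the presets.
- Decay-law selection near the mimicry floor is fragile by nature; MSE
  differences below ~1e−5 should not be read as family evidence.
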