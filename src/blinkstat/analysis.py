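"""Group-level analysis of RSVP curves.

Implements the analysis stage applied to every measure (first-target
accuracy, conditional second-target accuracy, swap probability, and
suppression ratios): aggregation of trial records into per-subject
curves, the classical two-way mixed ANOVA (between factor: group; within
factor: lag), per-lag two-sample simple effects, the baseline-match
check at a single long lag, and a Bayes factor for the group x lag
interaction in a mixed model with subject random intercepts.

The ANOVA uses the classical univariate sums-of-squares partition with
no sphericity correction, so with n subjects and k lags the group effect
has (1, n-2) degrees of freedom and the lag and interaction effects have
(k-1, (n-2)(k-1)).  It is computed directly from the wide
subjects-by-lags matrix, which makes Monte-Carlo replication loops cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .errors import DataError, FitError, MissingCellError, ParameterError
from .records import TRIAL_CSV_COLUMNS, SubjectLagCurve, TrialRecord

__all__ = [
    "AnovaEffect",
    "AnovaTable",
    "TTestResult",
    "BayesFactorResult",
    "pooled_t",
    "mixed_anova_matrix",
    "mixed_anova",
    "simple_effects_matrix",
    "simple_effects",
    "baseline_match_test",
    "aggregate_trials",
    "interaction_bayes_factor",
    "curves_to_matrix",
]


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaTable:
    group: AnovaEffect
    lag: AnovaEffect
    interaction: AnovaEffect

    def to_dict(self) -> dict:
        return {
            name: vars(getattr(self, name))
            for name in ("group", "lag", "interaction")
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class BayesFactorResult:
    bf_10: float
    method: str
    prior_spec: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# t tests


def pooled_t(x1: Sequence[float], x2: Sequence[float]) -> TTestResult:
    """Two-sample pooled-variance (Student) t test, two-tailed.

    Sign convention: mean(x2) - mean(x1), i.e. second sample minus first.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.size < 2 or x2.size < 2:
        raise DataError("each group needs at least 2 observations")
    df = x1.size + x2.size - 2
    sp2 = ((x1.size - 1) * x1.var(ddof=1) + (x2.size - 1) * x2.var(ddof=1)) / df
    if sp2 == 0.0:
        # zero-variance convention (deterministic toy fixtures)
        if x1.mean() == x2.mean():
            return TTestResult(t=0.0, df=float(df), p=1.0)
        raise DataError("zero within-group variance with unequal means: t is infinite")
    res = stats.ttest_ind(x2, x1, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# mixed ANOVA


def gg_epsilon(groups: np.ndarray, values: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon for the within factor.

    Computed from the pooled within-group covariance of the k repeated
    measures: eps = tr(CSC')^2 / ((k-1) tr((CSC')^2)) with C an
    orthonormal contrast basis; eps = 1 under perfect sphericity and
    1/(k-1) at the other extreme.
    """
    groups = np.asarray(groups)
    Y = np.asarray(values, float)
    k = Y.shape[1]
    centered = np.vstack(
        [Y[groups == g] - Y[groups == g].mean(axis=0) for g in np.unique(groups)]
    )
    S = centered.T @ centered / (Y.shape[0] - np.unique(groups).size)
    C = linalg.helmert(k)
    M = C @ S @ C.T
    denom = (k - 1) * float((M * M).sum())
    if denom <= 0:
        return 1.0
    return float(np.trace(M) ** 2 / denom)


def mixed_anova_matrix(
    groups: np.ndarray, values: np.ndarray, sphericity_correction: str = "none"
) -> AnovaTable:
    """Two-way mixed ANOVA from a wide subjects-by-lags matrix.

    ``groups`` holds one label per row of ``values``.  Unequal group
    sizes are allowed (the design stays proportional because every
    subject contributes every lag).  Zero-variance error terms yield the
    documented F=0, p=1 convention instead of NaN so fully deterministic
    toy fixtures run.

    ``sphericity_correction="gg"`` applies the Greenhouse-Geisser
    correction to the within-subject p values (lag and interaction):
    the reported integer degrees of freedom stay uncorrected, the p is
    evaluated at epsilon-scaled dfs.  Default is no correction.
    """
    if sphericity_correction not in ("none", "gg"):
        raise ParameterError(
            f"unknown sphericity correction {sphericity_correction!r}"
        )
    groups = np.asarray(groups)
    Y = np.asarray(values, float)
    if Y.ndim != 2 or groups.shape[0] != Y.shape[0]:
        raise DataError("values must be (n_subjects, n_lags) matching groups")
    if np.isnan(Y).any():
        raise MissingCellError("missing values in the subjects-by-lags matrix")
    n, k = Y.shape
    labels, inverse = np.unique(groups, return_inverse=True)
    n_groups = labels.size
    if n_groups < 2:
        raise DataError("need at least two groups")
    if k < 2:
        raise DataError("need at least two lags")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    lag_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())

    group_sizes = np.bincount(inverse)
    group_means = np.array([subj_means[inverse == g].mean() for g in range(n_groups)])
    ss_group = float(k * (group_sizes * (group_means - grand) ** 2).sum())
    ss_err_between = ss_subjects - ss_group

    ss_lag = float(n * ((lag_means - grand) ** 2).sum())
    cell_means = np.vstack([Y[inverse == g].mean(axis=0) for g in range(n_groups)])
    dev = cell_means - group_means[:, None] - lag_means[None, :] + grand
    ss_inter = float((group_sizes[:, None] * dev**2).sum())
    ss_err_within = ss_total - ss_subjects - ss_lag - ss_inter

    df_group, df_eb = n_groups - 1, n - n_groups
    df_lag = k - 1
    df_inter = (n_groups - 1) * (k - 1)
    df_ew = (n - n_groups) * (k - 1)

    eps = 1.0
    if sphericity_correction == "gg":
        eps = gg_epsilon(groups, Y)

    def effect(ss, df_num, ss_err, df_den, scale=1.0) -> AnovaEffect:
        ms_err = ss_err / df_den
        if ms_err <= 0 or ss < 0:
            # zero-variance convention, documented in the module docstring
            return AnovaEffect(F=0.0, df_num=df_num, df_den=df_den, p=1.0)
        F = (ss / df_num) / ms_err
        p = float(stats.f.sf(F, df_num * scale, df_den * scale))
        return AnovaEffect(F=float(F), df_num=df_num, df_den=df_den, p=p)

    return AnovaTable(
        group=effect(ss_group, df_group, ss_err_between, df_eb),
        lag=effect(ss_lag, df_lag, ss_err_within, df_ew, scale=eps),
        interaction=effect(ss_inter, df_inter, ss_err_within, df_ew, scale=eps),
    )


def curves_to_matrix(
    curves: Sequence[SubjectLagCurve], measure: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-subject curves into (groups, lags, values) arrays."""
    if not curves:
        raise DataError("no curves supplied")
    lags = curves[0].lags
    for c in curves:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise DataError("all subjects must share one lag grid (balanced design)")
    groups = np.array([c.group for c in curves])
    Y = np.vstack([c.measure(measure) for c in curves])
    return groups, lags, Y


def mixed_anova(curves: Sequence[SubjectLagCurve], measure: str) -> AnovaTable:
    """Two-way mixed ANOVA of one measure across subjects and lags."""
    groups, _, Y = curves_to_matrix(curves, measure)
    return mixed_anova_matrix(groups, Y)


def simple_effects_matrix(
    groups: np.ndarray, values: np.ndarray, holm: bool = False
) -> list[TTestResult]:
    """Independent two-sample pooled t per lag (column) between 2 groups."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise DataError("simple effects require exactly two groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    results = [pooled_t(a[:, j], b[:, j]) for j in range(values.shape[1])]
    if holm:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p for r in results], method="holm")[1]
        results = [
            TTestResult(t=r.t, df=r.df, p=float(p)) for r, p in zip(results, adj)
        ]
    return results


def simple_effects(
    curves: Sequence[SubjectLagCurve], measure: str, holm: bool = False
) -> list[TTestResult]:
    groups, _, Y = curves_to_matrix(curves, measure)
    return simple_effects_matrix(groups, Y, holm=holm)


def baseline_match_test(
    curves: Sequence[SubjectLagCurve], baseline_lag: float
) -> TTestResult:
    """Group comparison of first-target accuracy at one (long) lag.

    Used to verify that the presentation-rate manipulation matched the
    groups' baseline perceptual accuracy outside the blink window.
    """
    groups, lags, Y = curves_to_matrix(curves, "pr_t1")
    idx = np.where(np.isclose(lags, baseline_lag))[0]
    if idx.size == 0:
        raise DataError(f"lag {baseline_lag} not present in the curves")
    labels = np.unique(groups)
    if labels.size != 2:
        raise DataError("baseline match test requires exactly two groups")
    col = Y[:, idx[0]]
    return pooled_t(col[groups == labels[0]], col[groups == labels[1]])


# ---------------------------------------------------------------------------
# trial aggregation


def _score_trial(t1: str, t2: str, reported: tuple, scoring: str):
    if scoring == "position_free":
        t1_ok = t1 in reported
        t2_ok = t2 in reported
        swap = (
            t1_ok and t2_ok and reported.index(t2) < reported.index(t1)
        )
    elif scoring == "strict":
        t1_ok = len(reported) >= 1 and reported[0] == t1
        t2_ok = len(reported) >= 2 and reported[1] == t2
        swap = len(reported) >= 2 and reported[0] == t2 and reported[1] == t1
    else:
        raise DataError(f"unknown scoring rule {scoring!r}")
    return t1_ok, t2_ok, swap


def aggregate_trials(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    scoring: str = "position_free",
) -> list[SubjectLagCurve]:
    """Aggregate trial records into per-subject accuracy/swap curves.

    Triple-target trials are excluded.  Per subject and TOA:
    ``pr_t1`` is the fraction of dual trials with T1 reported (any
    position under the default scoring), ``pr_t2_given_t1`` the fraction
    of T1-correct trials with T2 also reported, and ``pr_swap`` the
    fraction of dual trials with both targets reported in reversed
    order.  Lags are TOA / 100 ms.
    """
    if isinstance(trials, pd.DataFrame):
        _validate_trial_frame(trials)
        records = _frame_to_records(trials)
    else:
        records = list(trials)
    if not records:
        raise DataError("no trials supplied")

    by_subject: dict[str, dict] = {}
    toas = sorted({r.toa_ms for r in records if r.condition == "dual"})
    for r in records:
        if r.condition != "dual":
            continue
        cell = by_subject.setdefault(
            r.subject_id, {"group": r.group, "counts": {}}
        )["counts"].setdefault(r.toa_ms, [0, 0, 0, 0])  # n, t1, t1&t2, swap
        t1_ok, t2_ok, swap = _score_trial(r.t1, r.t2, r.reported, scoring)
        cell[0] += 1
        cell[1] += t1_ok
        cell[2] += t1_ok and t2_ok
        cell[3] += swap

    curves = []
    for sid in sorted(by_subject):
        info = by_subject[sid]
        pr_t1, pr_t2, pr_swap = [], [], []
        for toa in toas:
            if toa not in info["counts"] or info["counts"][toa][0] == 0:
                raise MissingCellError(
                    f"subject {sid!r} has no dual trials at TOA {toa} ms"
                )
            n, n1, n12, nsw = info["counts"][toa]
            pr_t1.append(n1 / n)
            pr_t2.append(n12 / n1 if n1 else np.nan)
            pr_swap.append(nsw / n)
        curves.append(
            SubjectLagCurve(
                subject_id=sid,
                group=info["group"],
                lags=np.asarray(toas, float) / 100.0,
                pr_t1=np.asarray(pr_t1),
                pr_t2_given_t1=np.asarray(pr_t2),
                pr_swap=np.asarray(pr_swap),
            )
        )
    return curves


def _validate_trial_frame(df: pd.DataFrame) -> None:
    expected = TRIAL_CSV_COLUMNS
    for got, want in zip(df.columns, expected):
        if got != want:
            raise DataError(
                f"trial table header must be {expected}; first bad column: {got!r}"
            )
    if len(df.columns) != len(expected):
        raise DataError(f"trial table header must be exactly {expected}")


def _frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    df = df.fillna("")
    records = []
    for row in df.itertuples(index=False):
        reported = tuple(
            str(x) for x in (row.report_1, row.report_2, row.report_3) if str(x) != ""
        )
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                trial_index=int(row.trial_index),
                condition=str(row.condition),
                toa_ms=int(row.toa_ms),
                t1=str(row.t1),
                t2=str(row.t2),
                t3=str(row.t3),
                reported=reported,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Bayes factor for the group x lag interaction


#: Inverse-gamma prior scales on the effect-variance multipliers g:
#: fixed-effect blocks get InverseGamma(0.5, 0.25), the subject
#: random-intercept block gets the wider InverseGamma(0.5, 0.5).
PRIOR_SPEC = {
    "fixed": {"a": 0.5, "scale": 0.25},
    "random": {"a": 0.5, "scale": 0.5},
}


def interaction_bayes_factor(
    curves: Sequence[SubjectLagCurve],
    measure: str,
    method: str = "bic",
    nodes: int = 12,
) -> BayesFactorResult:
    """Bayes factor (alternative / null) for the group x lag interaction.

    Both models contain the group and lag main effects and subject
    random intercepts; the alternative adds the interaction.

    ``method="bic"`` fits both mixed models by maximum likelihood and
    uses the BIC approximation BF10 = exp((BIC_null - BIC_alt)/2).
    ``method="prior-integration"`` places zero-centred normal priors on
    sum-to-zero-coded effects whose variances are unknown multiples g of
    the error variance, with inverse-gamma priors on the g parameters
    (see :data:`PRIOR_SPEC`) and a 1/sigma^2 prior on the error
    variance; the marginal likelihoods are computed by Gauss-Legendre
    quadrature over the g parameters mapped through the prior inverse
    CDF.
    """
    groups, lags, Y = curves_to_matrix(curves, measure)
    if method == "bic":
        bf = _bf_bic(groups, lags, Y)
    elif method == "prior-integration":
        bf = _bf_prior_integration(groups, Y, nodes=nodes)
    else:
        raise ParameterError(f"unknown Bayes factor method {method!r}")
    return BayesFactorResult(bf_10=bf, method=method, prior_spec=PRIOR_SPEC)


def _long_frame(groups, lags, Y) -> pd.DataFrame:
    n, k = Y.shape
    return pd.DataFrame(
        {
            "y": Y.ravel(),
            "subject": np.repeat(np.arange(n), k),
            "group": np.repeat(groups, k),
            "lag": np.tile([f"L{x:g}" for x in lags], n),
        }
    )


def mixed_model_ml(groups, Y, interaction: bool) -> tuple[float, int]:
    """Exact ML log-likelihood of the random-intercept mixed model.

    For a balanced complete design, the compound-symmetric covariance
    decouples the likelihood into a within-subject part (error variance
    sigma^2, N(k-1) dimensions after removing subject means) and a
    between-subject part (subject means with variance psi/k where
    psi = sigma^2 + k tau^2).  The fixed effects (group, lag, optionally
    their interaction) are orthogonal to both, so their ML estimates are
    the cell means and the profile likelihood over the two variances is
    available in closed form, including the tau^2 = 0 boundary, where
    iterative fitters tend to fail.

    Returns (log-likelihood, number of free parameters).
    """
    groups = np.asarray(groups)
    Y = np.asarray(Y, float)
    n_subj, k = Y.shape
    labels, ginv = np.unique(groups, return_inverse=True)
    G = labels.size
    n = n_subj * k

    subj_means = Y.mean(axis=1)
    group_means = np.array([subj_means[ginv == g].mean() for g in range(G)])
    # between part: subject means about their group mean
    B = float(((subj_means - group_means[ginv]) ** 2).sum())

    # within part: deviations from subject means, minus lag (and
    # group x lag) structure
    W = Y - subj_means[:, None]
    lag_means = W.mean(axis=0)
    resid = W - lag_means[None, :]
    if interaction:
        cell = np.vstack([W[ginv == g].mean(axis=0) for g in range(G)])
        resid = W - cell[ginv]
    ss_w = float((resid**2).sum())

    df_w = n_subj * (k - 1)
    sigma2 = ss_w / df_w
    psi = k * B / n_subj  # ML of sigma^2 + k tau^2, unconstrained
    if psi < sigma2:  # tau^2 at the zero boundary: pool the variances
        sigma2 = psi = (ss_w + k * B) / n
    if sigma2 <= 0:
        raise FitError("degenerate data: zero residual variance in mixed model")
    llf = -0.5 * (
        n * np.log(2 * np.pi)
        + df_w * np.log(sigma2)
        + n_subj * np.log(psi)
        + ss_w / sigma2
        + k * B / psi
    )
    n_fixed = 1 + (G - 1) + (k - 1) + ((G - 1) * (k - 1) if interaction else 0)
    return float(llf), n_fixed + 2  # + tau^2 and sigma^2


def _bf_bic(groups, lags, Y) -> float:
    n = Y.size
    bics = {}
    for name, interaction in (("null", False), ("alt", True)):
        llf, k_params = mixed_model_ml(groups, Y, interaction)
        bics[name] = -2.0 * llf + np.log(n) * k_params
    return float(np.exp((bics["null"] - bics["alt"]) / 2.0))


def _sum_to_zero_basis(levels: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace, (levels, levels-1)."""
    return linalg.helmert(levels).T


def _design_blocks(groups: np.ndarray, n_lags: int, interaction: bool):
    """Column blocks (matrix, prior kind) for the g-prior mixed model."""
    labels, ginv = np.unique(groups, return_inverse=True)
    n_subj = groups.size
    n = n_subj * n_lags
    subj_idx = np.repeat(np.arange(n_subj), n_lags)
    lag_idx = np.tile(np.arange(n_lags), n_subj)

    Qg = _sum_to_zero_basis(labels.size)
    Ql = _sum_to_zero_basis(n_lags)
    Xg = Qg[ginv[subj_idx]]
    Xl = Ql[lag_idx]
    blocks = [(Xg, "fixed"), (Xl, "fixed")]
    if interaction:
        Xi = np.concatenate(
            [Xg[:, [i]] * Xl for i in range(Xg.shape[1])], axis=1
        )
        blocks.append((Xi, "fixed"))
    Z = np.zeros((n, n_subj))
    Z[np.arange(n), subj_idx] = 1.0
    blocks.append((Z, "random"))
    return blocks


def _log_marginal_on_grid(y, blocks, g_grid) -> np.ndarray:
    """log p(y | g) (up to a model-independent constant) for each g row.

    Integrating the effects, the grand mean (flat prior) and the error
    variance (1/sigma^2 prior) analytically leaves, with
    V = I + sum_j g_j X_j X_j':

        -1/2 log|V| - 1/2 log(1'V^-1 1) - (n-1)/2 log(y' P y)

    evaluated via the Woodbury identity on the p x p inner matrix.
    """
    U = np.concatenate([b for b, _ in blocks], axis=1)
    sizes = [b.shape[1] for b, _ in blocks]
    col_block = np.repeat(np.arange(len(blocks)), sizes)
    n = y.size
    M = U.T @ U
    uy = U.T @ y
    u1 = U.sum(axis=0)
    sy = float(y @ y)
    oy = float(y.sum())

    out = np.empty(g_grid.shape[0])
    chunk = 2048
    p = U.shape[1]
    eye = np.eye(p)
    for start in range(0, g_grid.shape[0], chunk):
        g = g_grid[start : start + chunk]
        s = np.sqrt(g[:, col_block])  # (B, p)
        A = eye[None] + s[:, :, None] * M[None] * s[:, None, :]
        sign, logdet = np.linalg.slogdet(A)
        w = np.stack([s * uy[None], s * u1[None]], axis=-1)  # (B, p, 2)
        z = np.linalg.solve(A, w)
        yVy = sy - np.einsum("bp,bp->b", w[..., 0], z[..., 0])
        oVo = n - np.einsum("bp,bp->b", w[..., 1], z[..., 1])
        yVo = oy - np.einsum("bp,bp->b", w[..., 0], z[..., 1])
        quad = yVy - yVo**2 / oVo
        out[start : start + chunk] = (
            -0.5 * logdet - 0.5 * np.log(oVo) - 0.5 * (n - 1) * np.log(quad)
        )
    return out


def _log_marginal(y, blocks, nodes: int) -> float:
    """Quadrature over the g parameters via the prior inverse CDF."""
    kinds = [kind for _, kind in blocks]
    z, w = np.polynomial.legendre.leggauss(nodes)
    z = 0.5 * (z + 1.0)  # map to (0, 1)
    w = 0.5 * w
    g_1d = []
    for kind in kinds:
        spec = PRIOR_SPEC[kind]
        g_1d.append(stats.invgamma.ppf(z, spec["a"], scale=spec["scale"]))
    mesh = np.meshgrid(*g_1d, indexing="ij")
    g_grid = np.stack([m.ravel() for m in mesh], axis=1)
    wmesh = np.meshgrid(*([w] * len(kinds)), indexing="ij")
    logw = np.log(np.prod(np.stack([m.ravel() for m in wmesh]), axis=0))
    logp = _log_marginal_on_grid(y, blocks, g_grid)
    return float(special.logsumexp(logp + logw))


def _bf_prior_integration(groups, Y, nodes: int = 12) -> float:
    n_lags = Y.shape[1]
    y = Y.ravel()
    log_alt = _log_marginal(y, _design_blocks(groups, n_lags, True), nodes)
    log_null = _log_marginal(y, _design_blocks(groups, n_lags, False), nodes)
    return float(np.exp(log_alt - log_null))
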