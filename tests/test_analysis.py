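"""Aggregation, mixed ANOVA, t tests and interaction Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import blinkstat as bs
from blinkstat.analysis import (
    PRIOR_SPEC,
    _design_blocks,
    _log_marginal,
    aggregate_trials,
    baseline_match_test,
    interaction_bayes_factor,
    mixed_anova_matrix,
    mixed_model_ml,
    pooled_t,
    simple_effects_matrix,
)
from blinkstat.errors import DataError, MissingCellError
from conftest import make_curves


def _trial(sid, toa, t1, t2, reported, condition="dual", t3=""):
    return bs.TrialRecord(
        subject_id=sid,
        group="g",
        trial_index=0,
        condition=condition,
        toa_ms=toa,
        t1=t1,
        t2=t2,
        t3=t3,
        reported=reported,
    )


class TestAggregateTrials:
    def test_perfect_reports(self):
        trials = [_trial("s1", 300, "2", "3", ("2", "3")) for _ in range(10)]
        (curve,) = aggregate_trials(trials)
        assert curve.pr_t1[0] == 1.0
        assert curve.pr_t2_given_t1[0] == 1.0
        assert curve.pr_swap[0] == 0.0
        assert curve.lags[0] == 3.0

    def test_hand_counted_mixture(self):
        """Four enumerated outcomes: ordered, reversed, T1-only, neither."""
        trials = [
            _trial("s1", 200, "2", "3", ("2", "3")),
            _trial("s1", 200, "2", "3", ("3", "2")),
            _trial("s1", 200, "2", "3", ("2",)),
            _trial("s1", 200, "2", "3", ()),
        ]
        (curve,) = aggregate_trials(trials)
        assert curve.pr_t1[0] == pytest.approx(0.75)
        assert curve.pr_t2_given_t1[0] == pytest.approx(2.0 / 3.0)
        assert curve.pr_swap[0] == pytest.approx(0.25)

    def test_triple_trials_excluded(self):
        trials = [_trial("s1", 200, "2", "3", ("2", "3")) for _ in range(4)] + [
            _trial("s1", 200, "2", "3", (), condition="triple", t3="4")
            for _ in range(4)
        ]
        (curve,) = aggregate_trials(trials)
        assert curve.pr_t1[0] == 1.0  # the empty triple reports don't count

    def test_missing_cell_names_the_cell(self):
        trials = [
            _trial("s1", 200, "2", "3", ("2", "3")),
            _trial("s2", 400, "2", "3", ("2", "3")),
        ]
        with pytest.raises(MissingCellError, match="s1.*400"):
            aggregate_trials(trials)

    def test_strict_scoring_requires_positions(self):
        trials = [
            _trial("s1", 200, "2", "3", ("3", "2")),  # reversed
            _trial("s1", 200, "2", "3", ("2", "3")),
        ]
        (curve,) = aggregate_trials(trials, scoring="strict")
        assert curve.pr_t1[0] == pytest.approx(0.5)
        assert curve.pr_swap[0] == pytest.approx(0.5)


class TestPooledT:
    def test_formula_oracle(self):
        """Independently coded pooled-t formula, machine precision."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n1, n2 = rng.integers(3, 30, 2)
            x1 = rng.normal(0.5, 0.2, n1)
            x2 = rng.normal(0.6, 0.3, n2)
            res = pooled_t(x1, x2)
            sp = np.sqrt(
                ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
            )
            t_expected = (x2.mean() - x1.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
            assert res.t == pytest.approx(t_expected, abs=1e-12)
            assert res.df == n1 + n2 - 2

    def test_identical_groups_give_zero(self):
        x = np.linspace(0.1, 0.9, 10)
        assert pooled_t(x, x).t == pytest.approx(0.0, abs=1e-12)


class TestBaselineMatch:
    def test_df_bookkeeping_with_24_per_group(self, lags8):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.05, (24, lags8.size))
        Y = np.vstack([0.85 + noise, 0.85 + noise])  # mirrored: equal means/vars
        curves = make_curves(["a"] * 24 + ["b"] * 24, Y, lags8, measure="pr_t1")
        res = baseline_match_test(curves, baseline_lag=8.0)
        assert res.df == 46
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_unknown_lag_rejected(self, lags8):
        curves = make_curves(["a"] * 3 + ["b"] * 3, np.ones((6, 8)) * 0.5, lags8,
                             measure="pr_t1")
        with pytest.raises(DataError):
            baseline_match_test(curves, baseline_lag=12.0)


class TestMixedAnova:
    def test_longhand_two_by_two_by_two(self):
        """Hand-worked sums of squares on 2 groups x 2 subjects x 2 lags.

        Data: group A subjects (2,3), (4,7); group B subjects (5,4), (8,9).
        grand = 42/8 = 5.25; subject means 2.5, 5.5, 4.5, 8.5;
        group means A=4, B=6.5; lag means 4.75, 5.75.
        SS_subjects = 2*[(2.75)^2+(0.25)^2+(0.75)^2+(3.25)^2] = 37.5
        SS_group    = 2*2*[(4-5.25)^2+(6.5-5.25)^2]           = 12.5
        SS_err_betw = 37.5 - 12.5 = 25, df 2  -> F_group = 12.5/12.5 = 1
        SS_lag      = 4*[0.25+0.25] = 2
        cell means: A (3,5), B (6.5,6.5); interaction deviations +-0.5
        SS_inter    = 2*4*0.25 = 2
        SS_total    = 43.5 -> SS_err_within = 43.5-37.5-2-2 = 2, df 2
        F_lag = 2/1 = 2, F_inter = 2/1 = 2.
        """
        Y = np.array([[2.0, 3.0], [4.0, 7.0], [5.0, 4.0], [8.0, 9.0]])
        groups = np.array(["A", "A", "B", "B"])
        table = mixed_anova_matrix(groups, Y)
        assert table.group.F == pytest.approx(1.0, abs=1e-12)
        assert (table.group.df_num, table.group.df_den) == (1, 2)
        assert table.lag.F == pytest.approx(2.0, abs=1e-12)
        assert table.interaction.F == pytest.approx(2.0, abs=1e-12)
        assert (table.interaction.df_num, table.interaction.df_den) == (1, 2)
        assert table.lag.p == pytest.approx(float(stats.f.sf(2.0, 1, 2)), abs=1e-12)

    def test_matches_pingouin_on_random_data(self):
        import pingouin as pg

        rng = np.random.default_rng(21)
        n1, n2, k = 12, 12, 5
        Y = rng.normal(0.6, 0.2, (n1 + n2, k))
        groups = np.array(["a"] * n1 + ["b"] * n2)
        mine = mixed_anova_matrix(groups, Y)

        df = pd.DataFrame(Y)
        df["subject"] = np.arange(n1 + n2)
        df["group"] = groups
        long = df.melt(id_vars=["subject", "group"], var_name="lag", value_name="y")
        ref = pg.mixed_anova(
            data=long, dv="y", within="lag", between="group",
            subject="subject", correction=False,
        ).set_index("Source")
        assert mine.group.F == pytest.approx(ref.loc["group", "F"], rel=1e-10)
        assert mine.lag.F == pytest.approx(ref.loc["lag", "F"], rel=1e-10)
        assert mine.interaction.F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-10)

    def test_gg_epsilon_matches_pingouin(self):
        import pingouin as pg

        from blinkstat.analysis import gg_epsilon

        rng = np.random.default_rng(61)
        n1, n2, k = 10, 10, 5
        Y = rng.normal(0.6, 0.2, (n1 + n2, k))
        Y[:, 0] += rng.normal(0, 0.3, n1 + n2)  # break sphericity
        groups = np.array(["a"] * n1 + ["b"] * n2)
        # cross-check against the library epsilon on group-centered data
        # (gg_epsilon pools the covariance within groups, so remove the
        # group means before handing the matrix to pingouin)
        centered = np.vstack([Y[:n1] - Y[:n1].mean(axis=0),
                              Y[n1:] - Y[n1:].mean(axis=0)])
        ref_eps = float(pg.epsilon(pd.DataFrame(centered), correction="gg"))
        eps = gg_epsilon(groups, Y)
        assert eps == pytest.approx(ref_eps, rel=0.02)
        corrected = mixed_anova_matrix(groups, Y, sphericity_correction="gg")
        plain = mixed_anova_matrix(groups, Y)
        assert corrected.lag.F == plain.lag.F  # only the p changes
        assert corrected.lag.p == pytest.approx(
            float(stats.f.sf(plain.lag.F, 4 * eps, 72 * eps)), abs=1e-12
        )

    def test_zero_variance_convention(self, lags8):
        Y = np.tile(np.full(8, 0.5), (6, 1))
        table = mixed_anova_matrix(np.array(["a"] * 3 + ["b"] * 3), Y)
        for eff in (table.group, table.lag, table.interaction):
            assert eff.F == 0.0 and eff.p == 1.0

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(0.5, 0.1, (10, 4))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        t1 = mixed_anova_matrix(groups, Y)
        t2 = mixed_anova_matrix(groups, Y + 3.7)
        assert t1.group.F == pytest.approx(t2.group.F, rel=1e-9)
        assert t1.lag.F == pytest.approx(t2.lag.F, rel=1e-9)
        assert t1.interaction.F == pytest.approx(t2.interaction.F, rel=1e-9)

    def test_group_f_invariant_to_lag_relabeling(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(0.5, 0.1, (10, 4))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(4)
        assert mixed_anova_matrix(groups, Y).group.F == pytest.approx(
            mixed_anova_matrix(groups, Y[:, perm]).group.F, rel=1e-12
        )

    @given(
        n1=st.integers(2, 10),
        n2=st.integers(2, 10),
        k=st.integers(2, 8),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25)
    def test_df_structure_property(self, n1, n2, k, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(0, 1, (n1 + n2, k))
        groups = np.array(["a"] * n1 + ["b"] * n2)
        t = mixed_anova_matrix(groups, Y)
        n = n1 + n2
        assert (t.group.df_num, t.group.df_den) == (1, n - 2)
        assert (t.lag.df_num, t.lag.df_den) == (k - 1, (n - 2) * (k - 1))
        assert (t.interaction.df_num, t.interaction.df_den) == (k - 1, (n - 2) * (k - 1))

    def test_full_null_rejection_rates(self):
        """Under iid noise with no group structure every effect rejects
        at the nominal level (400 replicates, 99% binomial interval)."""
        rng = np.random.default_rng(99)
        counts = {"group": 0, "lag": 0, "interaction": 0}
        n_rep = 400
        for _ in range(n_rep):
            Y = rng.normal(0.5, 0.1, (20, 4))
            groups = np.array(["a"] * 10 + ["b"] * 10)
            t = mixed_anova_matrix(groups, Y)
            for eff in counts:
                counts[eff] += getattr(t, eff).p < 0.05
        for eff, k in counts.items():
            ci = stats.binomtest(k, n_rep).proportion_ci(0.99, method="exact")
            assert ci.low <= 0.05 <= ci.high, f"{eff}: {k}/{n_rep}"

    def test_exp1_scale_df_structure(self, lags8):
        rng = np.random.default_rng(0)
        k = 7
        Y = rng.normal(0.7, 0.1, (48, k))
        groups = np.array(["patient"] * 24 + ["control"] * 24)
        t = mixed_anova_matrix(groups, Y)
        assert (t.group.df_num, t.group.df_den) == (1, 46)
        assert (t.lag.df_num, t.lag.df_den) == (6, 276)
        assert (t.interaction.df_num, t.interaction.df_den) == (6, 276)


class TestSimpleEffects:
    def test_identical_groups_all_zero(self, lags8):
        Y = np.tile(np.linspace(0.4, 0.8, 8), (10, 1))
        res = simple_effects_matrix(np.array(["a"] * 5 + ["b"] * 5), Y)
        assert all(abs(r.t) < 1e-12 for r in res)

    def test_baseline_shift_detected_at_all_lags(self, control_params, lags8):
        """A 0.16 baseline shift with the full uniform noise is detected
        at every lag in most replicates with n=100 per group."""
        from blinkstat.model import simulate_cohort

        n_rep, hits = 50, 0
        children = np.random.SeedSequence(17).spawn(n_rep)
        for child in children:
            cohort = simulate_cohort(
                control_params, -0.16, 100, lags8,
                np.random.default_rng(child), clip=False,
            )
            res = simple_effects_matrix(cohort.groups, cohort.values)
            hits += all(r.p < 0.05 for r in res)
        assert hits > n_rep / 2

    def test_matches_formula_per_lag(self):
        rng = np.random.default_rng(31)
        Y = rng.normal(0.5, 0.2, (12, 3))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = simple_effects_matrix(groups, Y)
        for j, r in enumerate(res):
            x1, x2 = Y[:6, j], Y[6:, j]
            sp = np.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2.0)
            t_expected = (x2.mean() - x1.mean()) / (sp * np.sqrt(2.0 / 6.0))
            assert r.t == pytest.approx(t_expected, abs=1e-12)


def _simulate_bf_dataset(rng, n_per_group=24, k=7, interaction_boost=0.0):
    """Balanced two-group curves with subject intercepts, no interaction
    unless interaction_boost widens the group gap at the second lag."""
    lag_effect = np.linspace(0.0, 0.2, k)
    subj = rng.normal(0.0, 0.08, 2 * n_per_group)
    Y = 0.6 + lag_effect[None, :] + subj[:, None] + rng.normal(0, 0.1, (2 * n_per_group, k))
    Y[n_per_group:] -= 0.05  # group main effect only
    if interaction_boost:
        Y[n_per_group:, 1] -= interaction_boost
    groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    return groups, Y


class TestInteractionBayesFactor:
    def test_closed_form_ml_matches_statsmodels(self):
        import warnings

        import statsmodels.formula.api as smf

        from blinkstat.analysis import _long_frame

        rng = np.random.default_rng(5)
        groups, Y = _simulate_bf_dataset(rng, n_per_group=10, k=4)
        for interaction in (False, True):
            llf, _ = mixed_model_ml(groups, Y, interaction)
            data = _long_frame(groups, np.arange(1.0, 5.0), Y)
            formula = "y ~ C(group) * C(lag)" if interaction else "y ~ C(group) + C(lag)"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = smf.mixedlm(formula, data, groups=data["subject"]).fit(reml=False)
            assert llf == pytest.approx(ref.llf, abs=1e-4)

    def test_null_data_favor_null_in_majority(self, lags8):
        rng = np.random.default_rng(41)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            groups, Y = _simulate_bf_dataset(rng)
            curves = make_curves(groups, Y, np.arange(1.0, 8.0))
            bf = interaction_bayes_factor(curves, "pr_t2_given_t1", method="bic")
            wins += bf.bf_10 < 1.0 / 3.0
        assert wins > n_rep / 2

    def test_large_interaction_favors_alternative(self):
        rng = np.random.default_rng(43)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            groups, Y = _simulate_bf_dataset(rng, interaction_boost=0.3)
            curves = make_curves(groups, Y, np.arange(1.0, 8.0))
            bf = interaction_bayes_factor(curves, "pr_t2_given_t1", method="bic")
            wins += bf.bf_10 > 3.0
        assert wins > n_rep / 2

    def test_prior_integration_matches_monte_carlo_oracle(self):
        """Quadrature marginal likelihood vs brute-force MC integration
        over the g parameters (dense linear algebra, 10^6 draws)."""
        rng = np.random.default_rng(11)
        groups = np.array(["a", "a", "b", "b"])
        Y = rng.normal(0.6, 0.15, (4, 2))
        Y[2:] += 0.1
        y = Y.ravel()
        blocks = _design_blocks(groups, 2, True)
        log_quad = _log_marginal(y, blocks, nodes=12)

        n = y.size
        Xs = [b for b, _ in blocks]
        kinds = [kind for _, kind in blocks]
        mc_rng = np.random.default_rng(99)
        logps = []
        for _ in range(10):
            m = 100_000
            gs = np.stack(
                [
                    stats.invgamma.rvs(
                        PRIOR_SPEC[kind]["a"],
                        scale=PRIOR_SPEC[kind]["scale"],
                        size=m,
                        random_state=mc_rng,
                    )
                    for kind in kinds
                ],
                axis=1,
            )
            V = np.broadcast_to(np.eye(n), (m, n, n)).copy()
            for j, X in enumerate(Xs):
                V += gs[:, j, None, None] * (X @ X.T)[None]
            _, logdet = np.linalg.slogdet(V)
            ones = np.ones(n)
            rhs = np.stack(
                [np.broadcast_to(y, (m, n)), np.broadcast_to(ones, (m, n))], axis=-1
            )
            sol = np.linalg.solve(V, rhs)
            yVy = np.einsum("i,mi->m", y, sol[..., 0])
            oVo = np.einsum("i,mi->m", ones, sol[..., 1])
            yVo = np.einsum("i,mi->m", ones, sol[..., 0])
            quad = yVy - yVo**2 / oVo
            logps.append(-0.5 * logdet - 0.5 * np.log(oVo) - 0.5 * (n - 1) * np.log(quad))
        logps = np.concatenate(logps)
        log_mc = special.logsumexp(logps) - np.log(logps.size)
        assert abs(np.exp(log_quad - log_mc) - 1.0) < 0.02

    def test_methods_agree_in_direction(self):
        """BIC and prior-integration point the same way on most datasets."""
        rng = np.random.default_rng(47)
        agree = 0
        n_rep = 10
        for i in range(n_rep):
            boost = 0.3 if i % 2 else 0.0
            groups, Y = _simulate_bf_dataset(rng, n_per_group=24, k=5,
                                             interaction_boost=boost)
            curves = make_curves(groups, Y, np.arange(1.0, 6.0))
            bic = interaction_bayes_factor(curves, "pr_t2_given_t1", method="bic")
            pi = interaction_bayes_factor(
                curves, "pr_t2_given_t1", method="prior-integration", nodes=8
            )
            agree += (bic.bf_10 < 1.0) == (pi.bf_10 < 1.0)
        assert agree >= 0.9 * n_rep
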