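"""Threshold-model Gibbs sampler: sub-step full conditionals against dense
oracles, seeded determinism, identification rescaling, and the DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invwishart

from hoofgen.gibbs import (
    PosteriorSamples,
    ThresholdGibbsSampler,
    compute_dic,
    gibbs_run,
)
from hoofgen.model import (
    DesignMatrices,
    ModelConfig,
    build_design,
    gaussian_trait,
    model_a_trait,
    model_b_trait,
)
from hoofgen.pedigree import a_inverse, parse_pedigree, relationship_matrix
from hoofgen.postgibbs import genetic_correlation, heritability


def founder_ped(n):
    return parse_pedigree(
        pd.DataFrame(
            {"id": [f"A{i}" for i in range(n)], "sire": ["0"] * n, "dam": ["0"] * n}
        )
    )


def design_for(ped, Y, traits, X=None):
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    if X is None:
        X = np.zeros((n, 0))
        cols = ()
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = tuple(f"x{j}" for j in range(X.shape[1]))
    return DesignMatrices(
        X=X,
        columns=cols,
        Y=Y,
        observed=~np.isnan(Y),
        animal=np.arange(n),
        traits=tuple(traits),
        ids=ped.ids[:n],
    )


def small_mixed_problem(seed=0, n=120):
    """Founder population, one binary + one Gaussian trait."""
    rng = np.random.default_rng(seed)
    ped = founder_ped(n)
    liab = rng.standard_normal(n)
    Y = np.column_stack(
        [(liab > 0).astype(float), rng.standard_normal(n)]
    )
    traits = (model_b_trait("D"), gaussian_trait("X"))
    des = design_for(ped, Y, traits, X=np.ones((n, 1)))
    cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                      n_iter=400, burn_in=100, thin=1, seed=seed)
    return des, a_inverse(ped), cfg


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        des, ai, cfg = small_mixed_problem(3)
        s1 = gibbs_run(des, ai, cfg)
        s2 = gibbs_run(des, ai, cfg)
        np.testing.assert_array_equal(s1.G, s2.G)
        np.testing.assert_array_equal(s1.R, s2.R)
        np.testing.assert_array_equal(s1.b, s2.b)
        np.testing.assert_array_equal(s1.u_mean, s2.u_mean)

    def test_different_seed_differs(self):
        des, ai, cfg = small_mixed_problem(3)
        s1 = gibbs_run(des, ai, cfg)
        s2 = gibbs_run(des, ai, cfg.with_(seed=4))
        assert not np.array_equal(s1.G, s2.G)


class TestLiabilities:
    def test_truncation_bounds_honoured_over_many_draws(self):
        """Binary score 1 -> liability >= 0; three-category scores stay in
        their threshold interval, over ~1e5 draws."""
        rng = np.random.default_rng(7)
        n = 400
        ped = founder_ped(n)
        y3 = rng.integers(0, 3, n).astype(float)
        y2 = rng.integers(0, 2, n).astype(float)
        traits = (model_a_trait("T3"), model_b_trait("T2"))
        des = design_for(ped, np.column_stack([y3, y2]), traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=7)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        for _ in range(250):  # 250 * 400 = 1e5 truncated draws per trait
            g.sweep()
            cut3 = g.cuts[0]
            for c in range(3):
                sel = g.ycat[:, 0] == c
                assert (g.liab[sel, 0] >= cut3[c]).all()
                assert (g.liab[sel, 0] <= cut3[c + 1]).all()
            assert (g.liab[g.ycat[:, 1] == 1, 1] >= 0).all()
            assert (g.liab[g.ycat[:, 1] == 0, 1] <= 0).all()

    def test_missing_cell_conditional_regression_on_observed_trait(self):
        """With residual correlation, the augmented liability of a missing
        cell must follow N(r * y_obs, 1 - r^2) (zero means, unit scales)."""
        n = 2000
        ped = founder_ped(n)
        rng = np.random.default_rng(8)
        y1 = rng.standard_normal(n)
        Y = np.column_stack([y1, np.full(n, np.nan)])
        traits = (gaussian_trait("A"), gaussian_trait("B"))
        des = design_for(ped, Y, traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=8)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        r = 0.8
        g.R = np.array([[1.0, r], [r, 1.0]])
        g.u[:] = 0.0
        draws = []
        for _ in range(50):
            g.sample_liabilities()
            draws.append(g.liab[:, 1].copy())
        draws = np.array(draws)
        resid = draws - r * y1  # conditional mean removed
        assert abs(resid.mean()) < 0.01
        assert resid.var() == pytest.approx(1 - r**2, rel=0.05)


class TestLocation:
    def test_fixed_effect_conditional_mean_is_record_value(self):
        """One founder, one Gaussian record, flat prior: b | u=0 must be
        N(y, R)."""
        ped = founder_ped(1)
        y = 3.7
        traits = (gaussian_trait("X"),)
        des = design_for(ped, [[y]], traits, X=[[1.0]])
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          n_iter=10, burn_in=1, seed=9)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        g.R = np.array([[1.0]])
        draws = []
        for _ in range(4000):
            g.b[:] = 0.0
            g.u[:] = 0.0
            g.sample_location()
            draws.append(g.b[0, 0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(y, abs=0.05)
        assert draws.var() == pytest.approx(1.0, rel=0.1)

    def test_u_sweep_leaves_dense_mvn_conditional_invariant(self):
        """20 animals, 2 traits: the Gauss-Seidel stationary distribution
        must match the dense closed-form N(mu, P^-1) with
        P = A^-1 (x) G^-1 + blockdiag(R^-1)."""
        rng = np.random.default_rng(10)
        ped = parse_pedigree(
            pd.DataFrame(
                {
                    "id": [f"A{i}" for i in range(20)],
                    "sire": ["0"] * 8 + [f"A{rng.integers(0, 4)}" for _ in range(12)],
                    "dam": ["0"] * 8 + [f"A{4 + rng.integers(0, 4)}" for _ in range(12)],
                }
            )
        )
        n = ped.n
        traits = (gaussian_trait("A"), gaussian_trait("B"))
        Y = rng.standard_normal((n, 2))
        des = design_for(ped, Y, traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=10)
        ai = a_inverse(ped)
        g = ThresholdGibbsSampler(des, ai, cfg)
        G = np.array([[0.5, 0.2], [0.2, 0.8]])
        R = np.array([[1.0, -0.3], [-0.3, 1.5]])
        g.G, g.R = G, R
        g.liab = Y.copy()
        # dense oracle, animal-major stacking
        P = np.kron(ai.toarray(), np.linalg.inv(G)) + np.kron(
            np.eye(n), np.linalg.inv(R)
        )
        rhs = (Y @ np.linalg.inv(R)).ravel()
        mu = np.linalg.solve(P, rhs).reshape(n, 2)
        cov = np.linalg.inv(P)
        draws = []
        for _ in range(6000):
            g.sample_location()
            draws.append(g.u.copy())
        draws = np.array(draws)[500:]
        np.testing.assert_allclose(draws.mean(axis=0), mu, atol=0.05)
        # spot-check variances for first animals, both traits
        for a in range(3):
            for t in range(2):
                got = draws[:, a, t].var()
                want = cov[a * 2 + t, a * 2 + t]
                assert got == pytest.approx(want, rel=0.15)

    def test_huge_residual_variance_shrinks_u_to_prior(self):
        des, ai, cfg = small_mixed_problem(11)
        traits = (gaussian_trait("X"),)
        n = 60
        ped = founder_ped(n)
        rng = np.random.default_rng(11)
        des = design_for(ped, rng.standard_normal((n, 1)) * 10, traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=11)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        g.G = np.array([[0.5]])
        g.R = np.array([[1e8]])
        g.liab = des.Y.copy()
        acc = []
        for _ in range(500):
            g.sample_location()
            acc.append(g.u.copy())
        acc = np.array(acc)
        # data uninformative: u ~ N(0, 0.5) regardless of the records
        assert abs(acc.mean()) < 0.05
        assert acc.var() == pytest.approx(0.5, rel=0.1)

    def test_unphenotyped_animal_follows_pedigree_prior(self):
        """Founder + child with no records: the stationary law of (u_A, u_C)
        is the pedigree prior N(0, A (x) G) with cov(u_A, u_C) = G/2."""
        ped = parse_pedigree(
            pd.DataFrame({"id": ["A", "C"], "sire": ["0", "A"], "dam": ["0", "0"]})
        )
        traits = (gaussian_trait("X"),)
        des = design_for(ped, np.full((0, 1), np.nan), traits)
        des = DesignMatrices(
            X=np.zeros((0, 0)), columns=(), Y=np.zeros((0, 1)),
            observed=np.zeros((0, 1), dtype=bool), animal=np.zeros(0, dtype=np.int64),
            traits=traits, ids=np.array([], dtype=object),
        )
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=12)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        gvar = 0.8
        g.G = np.array([[gvar]])
        draws = []
        for _ in range(20000):
            g.sample_location()
            draws.append(g.u[:, 0].copy())
        draws = np.array(draws)[1000:]
        assert draws[:, 0].var() == pytest.approx(gvar, rel=0.1)
        assert draws[:, 1].var() == pytest.approx(gvar, rel=0.1)
        got_cov = np.cov(draws.T)[0, 1]
        assert got_cov == pytest.approx(0.5 * gvar, rel=0.2)


class TestThresholds:
    def test_binary_threshold_fixed_at_zero(self):
        des, ai, cfg = small_mixed_problem(13)
        g = ThresholdGibbsSampler(des, ai, cfg)
        for _ in range(30):
            g.sweep()
            assert g.cuts[0][1] == 0.0

    def test_three_category_cutpoint_between_adjacent_liabilities(self):
        rng = np.random.default_rng(14)
        n = 300
        ped = founder_ped(n)
        y = rng.integers(0, 3, n).astype(float)
        traits = (model_a_trait("T"),)
        des = design_for(ped, y[:, None], traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=14)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        for _ in range(50):
            g.sweep()
            t2 = g.cuts[0][2]
            lo = g.liab[g.ycat[:, 0] == 1, 0].max()
            hi = g.liab[g.ycat[:, 0] == 2, 0].min()
            assert lo <= t2 <= hi
            assert np.all(np.diff(g.cuts[0][1:-1]) > 0) or g.cuts[0][1:-1].size == 1

    def test_empty_category_logged_and_bounded(self, caplog):
        import logging

        n = 200
        ped = founder_ped(n)
        y = np.zeros(n)
        y[:40] = 1.0  # category 2 never observed
        traits = (model_a_trait("T"),)
        des = design_for(ped, y[:, None], traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=15)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        with caplog.at_level(logging.WARNING):
            for _ in range(10):
                g.sweep()
        assert "empty category" in caplog.text
        assert np.isfinite(g.cuts[0][2])


class TestCovarianceUpdates:
    def test_g_full_conditional_matches_scipy_invwishart(self):
        """With u fixed, repeated G draws must match the scipy
        inverse-Wishart with scale S0 + u' A^-1 u (independent route)."""
        rng = np.random.default_rng(16)
        ped = founder_ped(30)
        traits = (gaussian_trait("A"), gaussian_trait("B"))
        des = design_for(ped, rng.standard_normal((30, 2)), traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=16,
                          prior_df_g=8.0)
        ai = a_inverse(ped)
        g = ThresholdGibbsSampler(des, ai, cfg)
        g.u = rng.standard_normal((30, 2))
        scale = cfg.prior_scale_g * np.eye(2) + g.u.T @ (ai @ g.u)
        expected = invwishart.mean(df=8.0 + 30, scale=scale)
        draws = []
        for _ in range(4000):
            g.sample_G()
            draws.append(g.G.copy())
            g.u = g.u  # u untouched by sample_G
        got = np.mean(draws, axis=0)
        np.testing.assert_allclose(got, expected, rtol=0.05, atol=0.005)

    def test_r_full_conditional_matches_scipy_invwishart(self):
        rng = np.random.default_rng(17)
        n = 50
        ped = founder_ped(n)
        traits = (gaussian_trait("A"), gaussian_trait("B"))
        Y = rng.standard_normal((n, 2))
        des = design_for(ped, Y, traits)
        cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                          intercept=False, n_iter=10, burn_in=1, seed=17,
                          prior_df_r=9.0)
        g = ThresholdGibbsSampler(des, a_inverse(ped), cfg)
        g.u[:] = 0.0
        g.liab = Y.copy()
        E = Y  # b = 0, u = 0
        scale = cfg.prior_scale_r * np.eye(2) + E.T @ E
        expected = invwishart.mean(df=9.0 + n, scale=scale)
        draws = []
        for _ in range(4000):
            g.sample_R()
            draws.append(g.R.copy())
        np.testing.assert_allclose(np.mean(draws, axis=0), expected,
                                   rtol=0.05, atol=0.005)

    def test_all_draws_positive_definite_and_ratios_bounded(self):
        des, ai, cfg = small_mixed_problem(18)
        s = gibbs_run(des, ai, cfg)
        for Gd in s.G:
            np.linalg.cholesky(Gd)
        h2 = heritability(s.G[:, 0, 0], s.R[:, 0, 0])
        assert ((h2 > 0) & (h2 < 1)).all()
        rg = genetic_correlation(s.G, 0, 1)
        assert ((rg >= -1) & (rg <= 1)).all()


class TestRescaling:
    def test_ordinal_residual_variance_exactly_one(self):
        des, ai, cfg = small_mixed_problem(19)
        s = gibbs_run(des, ai, cfg)
        np.testing.assert_array_equal(s.R[:, 0, 0], 1.0)
        assert (s.R[:, 1, 1] != 1.0).any()  # Gaussian trait not rescaled

    def test_correlations_invariant_under_rescale(self):
        des, ai, cfg = small_mixed_problem(20)
        g = ThresholdGibbsSampler(des, ai, cfg)
        g.G = np.array([[0.5, 0.25], [0.25, 0.9]])
        g.R = np.array([[2.0, 0.4], [0.4, 1.1]])
        rg_before = genetic_correlation(g.G, 0, 1)
        re_before = g.R[0, 1] / np.sqrt(g.R[0, 0] * g.R[1, 1])
        g.rescale()
        assert g.R[0, 0] == 1.0
        assert genetic_correlation(g.G, 0, 1) == pytest.approx(rg_before)
        assert g.R[0, 1] / np.sqrt(g.R[0, 0] * g.R[1, 1]) == pytest.approx(re_before)


class TestDIC:
    def test_identical_draws_have_zero_pd(self):
        """When every stored draw is the same, mean deviance equals the
        plug-in deviance and DIC = D(theta)."""
        des, ai, cfg = small_mixed_problem(21)
        s = gibbs_run(des, ai, cfg.with_(store_u=True, n_iter=250, burn_in=100,
                                         thin=1))
        j = 42
        S = 120
        tiled = PosteriorSamples(
            G=np.tile(s.G[j], (S, 1, 1)),
            R=np.tile(s.R[j], (S, 1, 1)),
            b=np.tile(s.b[j], (S, 1, 1)),
            thresholds={k: np.tile(v[j], (S, 1)) for k, v in s.thresholds.items()},
            deviance=np.full(S, s.deviance[j]),
            u_mean=s.u[j],
            traits=s.traits,
            columns=s.columns,
            seed=s.seed,
            config=s.config,
        )
        assert compute_dic(tiled, des) == pytest.approx(s.deviance[j], rel=1e-12)

    def test_needs_at_least_100_draws(self):
        des, ai, cfg = small_mixed_problem(22)
        s = gibbs_run(des, ai, cfg.with_(n_iter=150, burn_in=100, thin=1))
        with pytest.raises(ValueError, match="100"):
            compute_dic(s, des)

    def test_true_model_beats_null_on_strong_fixed_effect(self):
        """Gaussian trait with a strong sex effect: the model including sex
        must earn a lower DIC than the intercept-only null in most
        replicates."""
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            n = 250
            ped = founder_ped(n)
            sex = rng.integers(2, size=n).astype(float)
            y = 1.5 * sex + rng.standard_normal(n)
            traits = (gaussian_trait("X"),)
            X_full = np.column_stack([np.ones(n), sex])
            X_null = np.ones((n, 1))
            cfg = ModelConfig(traits=traits, fixed_effects=(), covariates=(),
                              n_iter=700, burn_in=200, thin=2, seed=400 + rep)
            ai = a_inverse(ped)
            dics = []
            for X in (X_full, X_null):
                des = design_for(ped, y[:, None], traits, X=X)
                s = gibbs_run(des, ai, cfg)
                dics.append(compute_dic(s, des))
            wins += dics[0] < dics[1]
        assert wins >= n_rep - 1

    def test_binary_coding_preferred_on_binary_generated_data(self):
        """Data generated by a single liability threshold, with the 1/2
        split pure noise: the dichotomous coding must earn the lower DIC."""
        rng = np.random.default_rng(23)
        n = 500
        ped = founder_ped(n)
        liab = rng.standard_normal(n)
        binary = (liab > 0).astype(float)
        three_cat = binary.copy()
        ones = np.flatnonzero(binary == 1)
        three_cat[rng.choice(ones, len(ones) // 2, replace=False)] = 2.0
        cfg_kw = dict(fixed_effects=(), covariates=(),
                      n_iter=1200, burn_in=400, thin=2)
        ai = a_inverse(ped)
        traits_a = (model_a_trait("T"),)
        des_a = design_for(ped, three_cat[:, None], traits_a, X=np.ones((n, 1)))
        s_a = gibbs_run(des_a, ai, ModelConfig(traits=traits_a, seed=24, **cfg_kw))
        traits_b = (model_b_trait("T"),)
        des_b = design_for(ped, binary[:, None], traits_b, X=np.ones((n, 1)))
        s_b = gibbs_run(des_b, ai, ModelConfig(traits=traits_b, seed=24, **cfg_kw))
        assert compute_dic(s_b, des_b) < compute_dic(s_a, des_a)
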