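"""Spline basis, design construction and GAMM engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepbrain import splines as sp


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0.0, 1.0, 200))
    y = x ** 2 + rng.normal(0.0, 0.05, x.size)
    return x, y


class TestCrBasis:
    def test_straight_line_has_zero_penalty(self, xy):
        x, _ = xy
        _, S, knots = sp.cr_basis(x, 10)
        beta = 2.0 + 3.0 * knots   # coefficients interpolating a line
        assert abs(beta @ S @ beta) < 1e-8

    def test_penalty_is_psd(self, xy):
        x, _ = xy
        _, S, _ = sp.cr_basis(x, 10)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_basis_interpolates_at_knots(self, xy):
        x, _ = xy
        _, _, knots = sp.cr_basis(x, 8)
        B = sp.cr_basis_at(knots, knots)
        assert np.allclose(B, np.eye(8), atol=1e-12)

    def test_unpenalized_fit_matches_least_squares(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10, center=False)], df,
                            intercept=False)
        fit = sp.fit_gamm(d, y, fixed_lambdas={"s(x)": [1e-300]})
        b_ols, *_ = np.linalg.lstsq(d.X, y, rcond=None)
        assert np.abs(d.X @ fit.beta - d.X @ b_ols).max() < 1e-8

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError):
            sp.cr_basis(np.array([0.0, 1.0, 1.0, 2.0]), 10)

    def test_linear_extrapolation_beyond_knots(self, xy):
        x, _ = xy
        _, _, knots = sp.cr_basis(x, 6)
        outside = np.array([knots[-1] + 0.5, knots[-1] + 1.0])
        B = sp.cr_basis_at(outside, knots)
        # second difference along extension is zero for every basis column
        inner = sp.cr_basis_at(np.array([knots[-1]]), knots)
        slope1 = B[0] - inner[0]
        slope2 = (B[1] - B[0])
        assert np.allclose(slope1 / 0.5, slope2 / 0.5, atol=1e-9)


class TestBuildDesign:
    def test_by_of_ones_equals_plain_smooth(self, xy):
        x, _ = xy
        df = pd.DataFrame({"x": x, "one": np.ones_like(x)})
        d_by = sp.build_design([sp.Smooth("x", k=8, by="one")], df)
        d_plain = sp.build_design([sp.Smooth("x", k=8)], df)
        sl_by = d_by.term("s(x):one").sl
        sl_pl = d_plain.term("s(x)").sl
        assert np.allclose(d_by.X[:, sl_by], d_plain.X[:, sl_pl])

    def test_tensor_dimensionality_before_constraint(self, xy):
        x, _ = xy
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": x, "z": rng.uniform(0, 1, x.size)})
        B1, _, _ = sp.cr_basis(df["x"].to_numpy(), 5)
        B2, _, _ = sp.cr_basis(df["z"].to_numpy(), 5)
        T = sp._row_kron(B1, B2)
        assert T.shape[1] == 25

    def test_centered_smooth_columns_sum_to_zero(self, xy):
        x, _ = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        cols = d.X[:, d.term("s(x)").sl]
        assert np.abs(cols.sum(axis=0)).max() < 1e-8 * len(df)

    def test_prediction_design_matches_training(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x, "z": y})
        d = sp.build_design([sp.Smooth("x", k=8), sp.Linear("z")], df)
        X2 = sp.design_matrix(d, df)
        assert np.allclose(X2, d.X, atol=1e-12)


class TestFitGamm:
    def test_fixed_lambda_matches_generalized_ridge(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        lam = 3.7
        fit = sp.fit_gamm(d, y, fixed_lambdas={"s(x)": [lam]})
        S = np.zeros((d.p, d.p))
        t = d.term("s(x)")
        S[t.sl, t.sl] = lam * t.penalties[0]
        b = np.linalg.solve(d.X.T @ d.X + S, d.X.T @ y)
        assert np.abs(fit.beta - b).max() < 1e-8

    def test_infinite_lambda_limit_is_straight_line(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        fit = sp.fit_gamm(d, y, fixed_lambdas={"s(x)": [1e8]})
        line = np.polyval(np.polyfit(x, y, 1), x)
        assert np.abs(d.X @ fit.beta - line).max() < 1e-4

    def test_zero_between_participant_variance(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        groups = np.arange(x.size) // 2
        fit = sp.fit_gamm(d, y, groups=groups)
        assert fit.sigma2_b < 0.05 * fit.sigma2

    def test_constant_response_degenerates(self, xy):
        x, _ = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        y = np.full(x.size, 3.0) + np.random.default_rng(0).normal(0, 1e-8, x.size)
        fit = sp.fit_gamm(d, y)
        assert fit.edf["s(x)"] <= 1.05
        assert abs(d.X @ fit.beta - 3.0).max() < 1e-4

    def test_random_intercept_variance_recovery(self):
        rng = np.random.default_rng(3)
        m, k = 150, 4
        g = np.repeat(np.arange(m), k)
        x = rng.uniform(-1, 1, m * k)
        y = 0.5 + np.sin(2 * x) + rng.normal(0, 1.2, m)[g] + \
            rng.normal(0, 0.8, m * k)
        d = sp.build_design([sp.Smooth("x", k=10)], pd.DataFrame({"x": x}))
        fit = sp.fit_gamm(d, y, groups=g)
        assert fit.sigma2_b == pytest.approx(1.44, rel=0.35)
        assert fit.sigma2 == pytest.approx(0.64, rel=0.25)

    def test_monotone_penalty_shrinks_edf(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        d = sp.build_design([sp.Smooth("x", k=10)], df)
        edfs = [sp.fit_gamm(d, y, fixed_lambdas={"s(x)": [lam]}).edf["s(x)"]
                for lam in (0.01, 1.0, 100.0, 1e4)]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_loglik_invariant_to_constraint_reparametrization(self, xy):
        # rotating the orthonormal basis that absorbs the sum-to-zero
        # constraint must leave the marginal likelihood unchanged
        import copy
        x, y = xy
        df = pd.DataFrame({"x": x})
        d1 = sp.build_design([sp.Smooth("x", k=8)], df)
        d2 = copy.deepcopy(d1)
        t = d2.term("s(x)")
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((t.Z.shape[1],) * 2))
        t.Z = t.Z @ Q
        t.penalties = [Q.T @ t.penalties[0] @ Q]
        d2.X = d2.X.copy()
        d2.X[:, t.sl] = d1.X[:, d1.term("s(x)").sl] @ Q
        f1 = sp.fit_gamm(d1, y, fixed_lambdas={"s(x)": [2.0]})
        f2 = sp.fit_gamm(d2, y, fixed_lambdas={"s(x)": [2.0]})
        assert f1.loglik_ml == pytest.approx(f2.loglik_ml, abs=1e-6)
        assert np.abs(d1.X @ f1.beta - d2.X @ f2.beta).max() < 1e-8


class TestPosteriorDraws:
    def test_centering_and_covariance(self, xy):
        x, y = xy
        d = sp.build_design([sp.Smooth("x", k=8)], pd.DataFrame({"x": x}))
        fit = sp.fit_gamm(d, y)
        draws = sp.posterior_draws(fit, 50_000, seed=5)
        mc_se = np.sqrt(np.diag(fit.V_beta) / 50_000)
        assert np.all(np.abs(draws.mean(0) - fit.beta) < 3.5 * mc_se + 1e-12)
        C = np.cov(draws.T)
        rel = np.linalg.norm(C - fit.V_beta) / np.linalg.norm(fit.V_beta)
        assert rel < 0.05

    def test_same_seed_identical(self, xy):
        x, y = xy
        d = sp.build_design([sp.Smooth("x", k=8)], pd.DataFrame({"x": x}))
        fit = sp.fit_gamm(d, y)
        a = sp.posterior_draws(fit, 100, seed=9)
        b = sp.posterior_draws(fit, 100, seed=9)
        assert np.array_equal(a, b)


class TestSmoothTermTest:
    def test_parametric_term_matches_ols_squared_t(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        n = 120
        x = rng.uniform(-1, 1, n)
        z = rng.uniform(-1, 1, n)
        y = 0.3 + 0.8 * x + 0.05 * z + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x": x, "z": z})
        d = sp.build_design([sp.Linear("x"), sp.Linear("z")], df)
        fit = sp.fit_gamm(d, y)
        F, edf, p = sp.smooth_term_test(fit, "z")
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit()
        assert p == pytest.approx(ols.pvalues[2], abs=5e-3)
        assert F == pytest.approx(ols.tvalues[2] ** 2, rel=1e-6)

    def test_edf_within_range(self, xy):
        x, y = xy
        d = sp.build_design([sp.Smooth("x", k=10)], pd.DataFrame({"x": x}))
        fit = sp.fit_gamm(d, y)
        assert 1.0 - 1e-6 <= fit.edf["s(x)"] <= 9.0


class TestLrt:
    def test_identical_models_give_zero(self, xy):
        x, y = xy
        d = sp.build_design([sp.Smooth("x", k=8)], pd.DataFrame({"x": x}))
        fit = sp.fit_gamm(d, y)
        stat, df, p, clamped = sp.lrt(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_nested_linear_models_match_closed_form(self):
        rng = np.random.default_rng(5)
        n = 150
        x = rng.uniform(-1, 1, n)
        z = rng.uniform(-1, 1, n)
        y = 0.2 + 0.9 * x + rng.normal(0, 0.4, n)
        df = pd.DataFrame({"x": x, "z": z})
        full = sp.fit_gamm(sp.build_design([sp.Linear("x"), sp.Linear("z")], df), y)
        red = sp.fit_gamm(sp.build_design([sp.Linear("x")], df), y)
        stat, _, _, _ = sp.lrt(full, red)

        def ml_ll(X):
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            s2 = r @ r / n
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

        Xf = np.column_stack([np.ones(n), x, z])
        Xr = np.column_stack([np.ones(n), x])
        assert stat == pytest.approx(2 * (ml_ll(Xf) - ml_ll(Xr)), abs=1e-6)

    def test_reduced_better_clamped_to_zero(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        f1 = sp.fit_gamm(sp.build_design([sp.Smooth("x", k=8)], df), y)
        f0 = sp.fit_gamm(sp.build_design([], df), y)
        stat, _, p, clamped = sp.lrt(f0, f1)  # deliberately swapped
        assert stat == 0.0 and clamped and p == 1.0

    def test_differing_row_counts_rejected(self, xy):
        x, y = xy
        df = pd.DataFrame({"x": x})
        f1 = sp.fit_gamm(sp.build_design([sp.Smooth("x", k=8)], df), y)
        f2 = sp.fit_gamm(sp.build_design([sp.Smooth("x", k=8)], df.iloc[:100]),
                         y[:100])
        with pytest.raises(ValueError):
            sp.lrt(f1, f2)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert sp.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_example(self):
        adj = sp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 40)
        ours = sp.bh_adjust(p)
        _, theirs, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sp.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=30))
    def test_monotone_in_sorted_order(self, ps):
        adj = sp.bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
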