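"""Spatial weights, OLS baseline, spatial-error ML, Nagelkerke, cutoffs."""

import numpy as np
import pytest
from scipy import optimize

from speciogeo.sar import (
    build_weights,
    fit_ols,
    fit_sar_error,
    fit_sar_lag,
    great_circle_degrees,
    nagelkerke_r2,
    select_cutoff,
)


def lattice(n_side, spacing=1.0):
    g = np.stack(
        np.meshgrid(np.arange(n_side) * spacing,
                    np.arange(n_side) * spacing, indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)
    return g


def simulate_error_process(w, X, beta, lam, sigma, rng):
    n = w.n
    eps = rng.normal(0.0, sigma, n)
    u = np.linalg.solve(np.eye(n) - lam * w.W, eps)
    Xc = np.column_stack([np.ones(n), X])
    return Xc @ beta + u


class TestWeights:
    def test_unit_distance_inverse_square(self):
        w = build_weights(np.array([[0.0, 0.0], [1.0, 0.0]]), 5.0,
                          row_standardize=False)
        assert w.W[0, 1] == pytest.approx(1.0)
        assert w.W[1, 0] == pytest.approx(1.0)
        assert w.W[0, 0] == 0.0

    def test_beyond_cutoff_isolated(self):
        w = build_weights(np.array([[0.0, 0.0], [10.0, 0.0]]), 5.0)
        assert np.all(w.W == 0)
        assert w.isolates.tolist() == [0, 1]

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-30, 30, size=(50, 2))
        w = build_weights(coords, 8.0, row_standardize=False)
        d = great_circle_degrees(coords)
        for i in range(50):
            for j in range(50):
                if i == j or d[i, j] > 8.0:
                    expect = 0.0
                else:
                    expect = 1.0 / d[i, j] ** 2
                assert w.W[i, j] == pytest.approx(expect, rel=1e-12)

    def test_row_standardized_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(30, 2))
        w = build_weights(coords, 5.0)
        sums = w.W.sum(axis=1)
        live = np.setdiff1d(np.arange(30), w.isolates)
        np.testing.assert_allclose(sums[live], 1.0)

    def test_coincident_sites_rejected(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="coincident"):
            build_weights(coords, 5.0)

    def test_great_circle_shrinks_with_latitude(self):
        # one degree of longitude is shorter at 60N than at the equator
        d_eq = great_circle_degrees(np.array([[0, 0], [0, 1]]))[0, 1]
        d_60 = great_circle_degrees(np.array([[60, 0], [60, 1]]))[0, 1]
        assert d_eq == pytest.approx(1.0, abs=1e-9)
        assert d_60 < 0.6


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = fit_ols(x, 2.0 + 3.0 * x)
        assert res.rsquared == pytest.approx(1.0)
        assert res.params[1] == pytest.approx(3.0)

    def test_three_point_closed_form(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.5])
        res = fit_ols(x, y)
        # closed-form slope = cov(x,y)/var(x)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / (
            (x - x.mean()) ** 2
        ).sum()
        assert res.params[1] == pytest.approx(slope, abs=1e-12)

    def test_independent_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        res = fit_ols(x, rng.normal(size=2000))
        assert abs(res.rsquared_adj) < 0.01

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            fit_ols(X, np.arange(6.0))


class TestSarError:
    def test_lambda_zero_data_reduces_to_ols(self):
        rng = np.random.default_rng(4)
        w = build_weights(lattice(12), 1.5)
        X = rng.normal(size=w.n)
        y = 1.0 + 0.5 * X + rng.normal(0, 0.4, w.n)
        fit = fit_sar_error(X, y, w, lambda_fixed=0.0)
        ols = fit_ols(X, y)
        np.testing.assert_allclose(
            fit.params.to_numpy(), ols.params, atol=1e-8
        )
        # free-lambda fits on independent-noise data hover around zero
        free = [
            fit_sar_error(
                X, 1.0 + 0.5 * X + rng.normal(0, 0.4, w.n), w
            ).lambda_spatial
            for _ in range(8)
        ]
        assert abs(np.mean(free)) < 0.15

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        w = build_weights(lattice(14), 1.5)
        X = rng.normal(size=w.n)
        lams, b1s = [], []
        for _ in range(15):
            y = simulate_error_process(w, X, (1.0, 0.5), 0.6, 0.3, rng)
            f = fit_sar_error(X, y, w)
            lams.append(f.lambda_spatial)
            b1s.append(f.params.iloc[1])
        assert abs(np.mean(lams) - 0.6) < 0.1
        assert abs(np.mean(b1s) - 0.5) < 0.05

    def test_profile_optimality(self):
        rng = np.random.default_rng(6)
        w = build_weights(lattice(10), 1.5)
        X = rng.normal(size=w.n)
        y = simulate_error_process(w, X, (0.5, 1.0), 0.4, 0.5, rng)
        f = fit_sar_error(X, y, w)
        from speciogeo.sar import _design, _profile_loglik_error

        Xc, _ = _design(X, w.n, None)
        eigs = w.eigenvalues()
        for lam in np.linspace(-0.9, 0.9, 21):
            ll, *_ = _profile_loglik_error(lam, y, Xc, w.W, eigs)
            assert f.loglik >= ll - 1e-9

    def test_matches_joint_optimisation_oracle(self):
        # independent route: direct Nelder-Mead over (beta, lambda,
        # log sigma2) with slogdet, no profiling, no eigenvalues
        rng = np.random.default_rng(7)
        w = build_weights(lattice(8), 1.5)
        n = w.n
        X = rng.normal(size=n)
        Xc = np.column_stack([np.ones(n), X])

        def negll(theta, y):
            beta, lam, lsig = theta[:2], theta[2], theta[3]
            s2 = np.exp(lsig)
            A = np.eye(n) - lam * w.W
            e = A @ (y - Xc @ beta)
            _, logdet = np.linalg.slogdet(A)
            return (0.5 * n * np.log(2 * np.pi * s2)
                    + 0.5 * e @ e / s2 - logdet)

        for _ in range(3):
            y = simulate_error_process(w, X, (1.0, 0.5), 0.5, 0.4, rng)
            f = fit_sar_error(X, y, w)
            r = optimize.minimize(
                negll, np.r_[0.0, 0.0, 0.0, 0.0], args=(y,),
                method="Nelder-Mead",
                options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-13},
            )
            np.testing.assert_allclose(f.params.to_numpy(), r.x[:2],
                                       atol=1e-4)
            assert abs(f.lambda_spatial - r.x[2]) < 1e-4
            assert abs(f.loglik + r.fun) < 1e-3

    def test_nonfinite_response_rejected(self):
        w = build_weights(lattice(3), 1.5)
        y = np.ones(w.n)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_sar_error(None, y, w)


class TestNagelkerke:
    def test_zero_when_no_improvement(self):
        assert nagelkerke_r2(-150.0, -150.0, 100) == 0.0

    def test_worked_case(self):
        # n=100, logL0=-150, logL1=-120:
        # CS = 1 - exp((2/100)(-30)); max = 1 - exp((2/100)(-150))
        val = nagelkerke_r2(-120.0, -150.0, 100)
        expect = (1 - np.exp(-0.6)) / (1 - np.exp(-3.0))
        assert val == pytest.approx(expect, abs=1e-12)

    def test_saturated_limit_is_one(self):
        assert nagelkerke_r2(0.0, -80.0, 50) == pytest.approx(1.0)

    def test_warns_when_alternative_below_null(self):
        with pytest.warns(UserWarning, match="below null"):
            nagelkerke_r2(-160.0, -150.0, 100)


class TestSelectCutoff:
    def test_single_candidate_trivial(self):
        rng = np.random.default_rng(8)
        coords = lattice(7)
        X = rng.normal(size=len(coords))
        y = 1.0 + 0.3 * X + rng.normal(0, 0.3, len(coords))
        best, table, fit = select_cutoff(X, y, coords, [2.0])
        assert best == 2.0
        assert len(table) == 1

    def test_aic_identity_audit(self):
        rng = np.random.default_rng(9)
        coords = lattice(7)
        X = rng.normal(size=len(coords))
        y = 1.0 + 0.3 * X + rng.normal(0, 0.3, len(coords))
        best, table, fit = select_cutoff(X, y, coords, [1.5, 3.0, 6.0])
        # AIC = 2k - 2 logLik with k = 2 betas + lambda + sigma2
        np.testing.assert_allclose(
            table["aic"], 2 * 4 - 2 * table["loglik"]
        )
        assert table.loc[best, "aic"] == table["aic"].min()

    def test_lag_model_available(self):
        rng = np.random.default_rng(10)
        w = build_weights(lattice(7), 1.5)
        X = rng.normal(size=w.n)
        y = 0.5 + 0.4 * X + rng.normal(0, 0.3, w.n)
        f = fit_sar_lag(X, y, w)
        assert np.isfinite(f.loglik)
        assert -1 < f.lambda_spatial < 1
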