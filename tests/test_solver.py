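"""Readout/tail solver: oracle equivalence, descent, recovery, determinism.

The exact block-coordinate-descent configuration (both readout blocks fit on
all columns, dropout off) carries the provable properties; tests construct
it explicitly via ``bcd_options``.
"""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize

from autoreservoir import (
    SolvabilityError,
    SolverOptions,
    build_hankel,
    solve_arnn,
    solve_linear_sti,
    update_readout,
    update_tail,
)


def bcd_options(**kw):
    base = dict(
        dropout_rate=0.0,
        a_fit_columns="all",
        b_fit_columns="all",
        tail_smoothing=0.0,
        max_iter=500,
        tol=1e-12,
    )
    base.update(kw)
    return SolverOptions(**base)


# ---------------------------------------------------------------- oracles


def oracle_objective(A, B, tail, FX, y_known, L, ridge, gamma):
    """Independent evaluation of the penalized least-squares functional."""
    series = np.concatenate([y_known, tail])
    Y = sliding_window_view(series, L).T
    j = np.sum((A @ FX - Y) ** 2) + np.sum((FX - B @ Y) ** 2)
    j += gamma * np.sum((A @ B - np.eye(L)) ** 2)
    j += ridge * (np.sum(A**2) + np.sum(B**2))
    return float(j)


def oracle_gradient(A, B, tail, FX, y_known, L, ridge, gamma):
    series = np.concatenate([y_known, tail])
    Y = sliding_window_view(series, L).T
    m = y_known.shape[0]
    R1 = A @ FX - Y
    R2 = FX - B @ Y
    C = A @ B - np.eye(L)
    dA = 2 * R1 @ FX.T + 2 * gamma * C @ B.T + 2 * ridge * A
    dB = -2 * R2 @ Y.T + 2 * gamma * A.T @ C + 2 * ridge * B
    dY = -2 * R1 - 2 * B.T @ R2
    dtail = np.zeros(L - 1)
    for i in range(L):
        for t in range(m):
            k = t + i
            if k >= m:
                dtail[k - m] += dY[i, t]
    return dA, dB, dtail


def brute_force_minimum(FX, y_known, L, ridge, gamma, n_starts=10, seed=0):
    """Multi-start quasi-Newton minimization over (A, B, tail) jointly."""
    d, m = FX.shape
    nA, nB = L * d, d * L
    rng = np.random.default_rng(seed)

    def fun(theta):
        A = theta[:nA].reshape(L, d)
        B = theta[nA : nA + nB].reshape(d, L)
        tail = theta[nA + nB :]
        j = oracle_objective(A, B, tail, FX, y_known, L, ridge, gamma)
        dA, dB, dt = oracle_gradient(A, B, tail, FX, y_known, L, ridge, gamma)
        return j, np.concatenate([dA.ravel(), dB.ravel(), dt])

    best = np.inf
    for _ in range(n_starts):
        theta0 = rng.normal(scale=0.5, size=nA + nB + L - 1)
        res = minimize(
            fun, theta0, jac=True, method="L-BFGS-B",
            options=dict(maxiter=20_000, ftol=1e-18, gtol=1e-14),
        )
        best = min(best, res.fun)
    return best


# ---------------------------------------------------------------- tests


def test_brute_force_oracle_equivalence(rng):
    """On tiny instances the solver's converged J equals the global minimum
    found by multi-start joint minimization, within 1e-6."""
    for m, L, d, seed in [(8, 3, 6, 0), (6, 2, 4, 1), (8, 3, 5, 2)]:
        FX = rng.normal(size=(d, m))
        y = rng.normal(size=m)
        lam, gam = 0.5, 1.0
        sol = solve_arnn(FX, y, L, bcd_options(ridge=lam, consistency_weight=gam, max_iter=5000))
        j_solver = oracle_objective(
            sol.A, sol.B, sol.forecast, FX, y, L, lam, gam
        )
        j_oracle = brute_force_minimum(FX, y, L, lam, gam, seed=seed)
        assert abs(j_solver - j_oracle) <= 1e-6


def test_constructed_consistency_recovers_tail(rng):
    """Data generated to satisfy both equations exactly is recovered."""
    L, d, m = 3, 6, 12
    A_star = rng.normal(size=(L, d))
    B_star = A_star.T @ np.linalg.inv(A_star @ A_star.T)  # right inverse
    series = np.cumsum(rng.normal(size=m + L - 1))  # smooth-ish random walk
    Y = sliding_window_view(series, L).T
    FX = B_star @ Y
    sol = solve_arnn(
        FX, series[:m], L, bcd_options(ridge=1e-10, max_iter=5000)
    )
    rel = np.linalg.norm(sol.forecast - series[m:]) / np.linalg.norm(series[m:])
    assert rel <= 1e-6


def test_single_unknown_matches_grid_oracle(rng):
    """For L=2 the tail update equals a 1-D grid minimization of J."""
    L, d, m = 2, 4, 6
    FX = rng.normal(size=(d, m))
    y = rng.normal(size=m)
    A = rng.normal(size=(L, d))
    B = rng.normal(size=(d, L))
    h = build_hankel(y, L)
    h.fill(np.zeros(1))
    u = update_tail(FX, A, B, h)[0]

    grid = np.arange(-4.0, 4.0, 1e-4)
    js = [
        oracle_objective(A, B, np.array([g]), FX, y, L, 0.0, 0.0) for g in grid
    ]
    g_best = grid[int(np.argmin(js))]
    assert abs(u - g_best) <= 1e-3


def test_monotone_objective_descent_without_dropout(rng):
    d, m, L = 12, 30, 4
    FX = np.tanh(rng.normal(size=(d, m)))
    y = rng.normal(size=m).cumsum()
    sol = solve_arnn(FX, y, L, bcd_options(ridge=0.1, max_iter=50, tol=1e-16))
    obj = np.asarray(sol.diagnostics.objective)
    assert np.all(np.isfinite(obj))
    assert np.all(np.diff(obj) <= 1e-9 * max(1.0, obj[0]))


def test_exact_recovery_noiseless_linear_system(rng):
    """A linear system whose trajectory lives in a low-dimensional subspace
    is forecast to relative RMSE <= 1e-3."""
    r, D, L, m = 3, 12, 5, 200
    th = 0.35
    S = np.zeros((r, r))
    S[:2, :2] = 0.998 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    S[2, 2] = 0.97
    U, _ = np.linalg.qr(rng.normal(size=(D, r)))
    z = rng.normal(size=r)
    Z = np.empty((r, m + L - 1))
    for t in range(m + L - 1):
        Z[:, t] = z
        z = S @ z
    X = U @ Z
    y = X[0]
    sol = solve_linear_sti(
        X[:, :m], y[:m], L, SolverOptions(dropout_rate=0.0, ridge=1e-10, tail_smoothing=0.0)
    )
    rel = np.linalg.norm(sol.forecast - y[m:]) / np.linalg.norm(y[m:])
    assert rel <= 1e-3


def test_identity_reservoir_equals_linear_solver(rng):
    X = rng.normal(size=(8, 20))
    y = X[2]
    opts = SolverOptions(dropout_rate=0.2, seed=77)
    a = solve_arnn(X, y, 3, opts)
    b = solve_linear_sti(X, y, 3, opts)
    np.testing.assert_array_equal(a.forecast, b.forecast)
    np.testing.assert_array_equal(a.A, b.A)
    np.testing.assert_array_equal(a.B, b.B)


def test_constant_series_fixed_point():
    D, m, L = 5, 12, 3
    c = 2.5
    X = np.tile(np.array([[1.0], [-0.5], [2.5], [0.3], [4.0]]), (1, m))
    y = np.full(m, c)
    sol = solve_arnn(X, y, L, bcd_options(ridge=1e-8))
    np.testing.assert_allclose(sol.forecast, c, atol=1e-8)


def test_graceful_degradation_with_noise(rng):
    """Forecast error grows continuously (no blow-up) as observation noise
    increases from zero on a linear system."""
    r, D, L, m = 2, 10, 4, 120
    th = 0.3
    S = 0.999 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    U, _ = np.linalg.qr(rng.normal(size=(D, r)))
    z = np.array([1.0, 0.0])
    Z = np.empty((r, m + L - 1))
    for t in range(m + L - 1):
        Z[:, t] = z
        z = S @ z
    X0 = U @ Z
    errs = []
    for sigma in (0.0, 0.01, 0.05):
        X = X0 + rng.normal(scale=sigma, size=X0.shape)
        y = X[0]
        sol = solve_linear_sti(X[:, :m], y[:m], L, SolverOptions(dropout_rate=0.0, ridge=1e-6, tail_smoothing=0.0))
        errs.append(np.sqrt(np.mean((sol.forecast - X0[0, m:]) ** 2)))
    assert errs[0] < 1e-3
    assert all(e < 1.0 for e in errs)  # no catastrophic blow-up


class TestUpdateReadout:
    def test_exact_fit_residual(self, rng):
        L, d, m = 3, 5, 40
        A_star = rng.normal(size=(L, d))
        FX = rng.normal(size=(d, m))
        Y = A_star @ FX
        A, B = update_readout(FX, Y, ridge=1e-10, consistency_weight=0.0)
        assert np.linalg.norm(A @ FX - Y) <= 1e-6

    def test_large_ridge_shrinks_to_zero(self, rng):
        FX = rng.normal(size=(5, 20))
        Y = rng.normal(size=(3, 20))
        A, B = update_readout(FX, Y, ridge=1e12, consistency_weight=1.0)
        assert np.abs(A).max() < 1e-6 and np.abs(B).max() < 1e-6

    def test_dropped_feature_has_no_weight(self, rng):
        d, m, L = 6, 25, 3
        FX = rng.normal(size=(d, m))
        Y = rng.normal(size=(L, m))
        mask = np.ones(d, dtype=bool)
        mask[2] = False
        A, B = update_readout(
            FX, Y, ridge=1e-3, consistency_weight=1.0, dropout_mask=mask
        )
        np.testing.assert_allclose(A[:, 2], 0.0, atol=1e-10)
        np.testing.assert_allclose(B[2, :], 0.0, atol=1e-10)


class TestUpdateTail:
    def test_fixed_point_after_convergence(self, rng):
        d, m, L = 10, 25, 4
        FX = np.tanh(rng.normal(size=(d, m)))
        y = rng.normal(size=m).cumsum()
        sol = solve_arnn(FX, y, L, bcd_options(ridge=0.1, max_iter=2000))
        h = build_hankel(y, L)
        h.fill(sol.forecast)
        again = update_tail(FX, sol.A, sol.B, h)
        np.testing.assert_allclose(again, sol.forecast, atol=1e-6)

    def test_dominant_smoothing_gives_affine_tail(self, rng):
        """As the smoothness prior dominates, the tail becomes an affine
        continuation of the last observed value (zero second differences),
        with the slope still chosen by the data terms."""
        d, m, L = 6, 10, 5
        FX = rng.normal(size=(d, m))
        y = rng.normal(size=m)
        A = rng.normal(size=(L, d))
        B = rng.normal(size=(d, L))
        h = build_hankel(y, L)
        h.fill(np.zeros(L - 1))
        tail = update_tail(FX, A, B, h, tail_smoothing=1e12)
        ext = np.concatenate([[y[-1]], tail])
        np.testing.assert_allclose(np.diff(ext, n=2), 0.0, atol=1e-4)

    def test_primary_only_matches_cell_average(self, rng):
        """With the conjugate channel off, each unknown is the mean of the
        primary predictions over all Hankel cells containing it."""
        d, m, L = 5, 8, 3
        FX = rng.normal(size=(d, m))
        y = rng.normal(size=m)
        A = rng.normal(size=(L, d))
        B = rng.normal(size=(d, L))
        h = build_hankel(y, L)
        h.fill(np.zeros(L - 1))
        tail = update_tail(FX, A, B, h, primary_weight=1.0, conjugate_weight=0.0)
        P = A @ FX
        expected = np.zeros(L - 1)
        counts = np.zeros(L - 1)
        for i in range(L):
            for t in range(m):
                k = t + i
                if k >= m:
                    expected[k - m] += P[i, t]
                    counts[k - m] += 1
        np.testing.assert_allclose(tail, expected / counts, atol=1e-10)


class TestContracts:
    def test_solvability_requires_more_features_than_L(self, rng):
        FX = rng.normal(size=(3, 10))
        with pytest.raises(SolvabilityError):
            solve_arnn(FX, rng.normal(size=10), L=3)
        with pytest.raises(SolvabilityError):
            solve_linear_sti(FX, rng.normal(size=10), L=4)

    def test_singular_normal_equations_advice(self, rng):
        FX = np.outer(rng.normal(size=4), rng.normal(size=10))  # rank 1
        opts = bcd_options(ridge=0.0, consistency_weight=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            solve_arnn(FX, rng.normal(size=10), 2, opts)

    def test_nonconvergence_returns_best_iterate(self, rng):
        FX = np.tanh(rng.normal(size=(8, 20)))
        y = rng.normal(size=20).cumsum()
        sol = solve_arnn(FX, y, 4, SolverOptions(max_iter=2, tol=1e-16))
        assert not sol.diagnostics.converged
        assert sol.diagnostics.iterations == 2
        assert np.all(np.isfinite(sol.forecast))

    def test_forecast_is_series_tail_and_gap_reported(self, rng):
        FX = np.tanh(rng.normal(size=(9, 22)))
        y = rng.normal(size=22).cumsum()
        sol = solve_arnn(FX, y, 4)
        np.testing.assert_array_equal(sol.forecast, sol.completed_series[-3:])
        np.testing.assert_array_equal(sol.completed_series[:22], y)
        assert np.isfinite(sol.diagnostics.ab_identity_gap)
        assert sol.diagnostics.ab_identity_gap >= 0

    def test_seeded_determinism_with_dropout(self, rng):
        FX = np.tanh(rng.normal(size=(10, 24)))
        y = rng.normal(size=24).cumsum()
        opts = SolverOptions(dropout_rate=0.3, seed=5)
        a = solve_arnn(FX, y, 3, opts)
        b = solve_arnn(FX, y, 3, opts)
        np.testing.assert_array_equal(a.forecast, b.forecast)
        c = solve_arnn(FX, y, 3, SolverOptions(dropout_rate=0.3, seed=6))
        assert not np.array_equal(a.forecast, c.forecast)
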