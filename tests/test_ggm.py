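import numpy as np
import pytest
from scipy.optimize import minimize

from symptomnet import (
    default_target,
    fit_ggm,
    loocv_select,
    partial_correlations,
    ridge_precision,
    sample_covariance,
)


def random_spd(rng, p, extra=2):
    A = rng.standard_normal((p, p + extra))
    return A @ A.T / (p + extra)


def penalized_mle_oracle(S, lam, T):
    """Numerical maximizer of log det(O) - tr(SO) - lam/2 ||O - T||_F^2,
    parametrized by a Cholesky factor with log-diagonal. Independent of the
    closed form under test."""
    p = S.shape[0]
    tril = np.tril_indices(p)

    def unpack(theta):
        L = np.zeros((p, p))
        L[tril] = theta
        d = np.diag_indices(p)
        L[d] = np.exp(L[d])
        return L

    def negobj_and_grad(theta):
        L = unpack(theta)
        O = L @ L.T
        _, logdet = np.linalg.slogdet(O)
        f = -(logdet - np.trace(S @ O) - lam / 2 * np.sum((O - T) ** 2))
        G = -(np.linalg.inv(O) - S - lam * (O - T))
        GL = 2 * (G @ L)
        grad = np.zeros((p, p))
        grad[tril] = GL[tril]
        d = np.diag_indices(p)
        grad[d] = GL[d] * L[d]
        return f, grad[tril]

    res = minimize(negobj_and_grad, np.zeros(len(tril[0])), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    L = unpack(res.x)
    return L @ L.T


def loocv_oracle(X, grid, T):
    """Brute-force LOOCV: an explicit double loop, no shared precomputation."""
    n, p = X.shape
    means = np.zeros(len(grid))
    for g, lam in enumerate(grid):
        total = 0.0
        for i in range(n):
            rest = np.delete(X, i, axis=0)
            mu = rest.mean(axis=0)
            Xc = rest - mu
            Si = Xc.T @ Xc / (n - 1)
            O = ridge_precision(Si, lam, T)
            r = X[i] - mu
            total += 0.5 * (p * np.log(2 * np.pi)
                            - np.linalg.slogdet(O)[1] + r @ O @ r)
        means[g] = total / n
    return means


class TestSampleCovariance:
    def test_duplicated_column_matches_diagonal(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        S = sample_covariance(X)
        assert S[0, 1] == pytest.approx(S[0, 0], abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        S = sample_covariance(rng.standard_normal((10_000, 4)))
        off = S[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.05

    def test_three_by_two_hand_computation(self):
        X = np.array([[1.0, 2.0], [3.0, 0.0], [5.0, 4.0]])
        # column means (3, 2); 1/n convention
        expected = np.array(
            [
                [((-2) ** 2 + 0 + 2**2) / 3, ((-2) * 0 + 0 * (-2) + 2 * 2) / 3],
                [((-2) * 0 + 0 * (-2) + 2 * 2) / 3, (0 + 4 + 4) / 3],
            ]
        )
        assert np.allclose(sample_covariance(X), expected, atol=1e-12)


class TestRidgePrecision:
    def test_identity_fixed_point(self):
        # gradient O^{-1} - S - lam (O - T) vanishes at O = I when S = T = I
        for lam in (1e-3, 0.125, 1.0, 100.0):
            O = ridge_precision(np.eye(4), lam, np.eye(4))
            assert np.allclose(O, np.eye(4), atol=1e-12)

    def test_tiny_penalty_recovers_inverse_covariance(self):
        rng = np.random.default_rng(2)
        S = random_spd(rng, 4, extra=20)
        O = ridge_precision(S, 1e-8, np.zeros((4, 4)))
        assert np.abs(O - np.linalg.inv(S)).max() < 1e-4

    def test_matches_numerical_maximizer(self):
        rng = np.random.default_rng(3)
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        O = ridge_precision(S, 0.1, np.zeros((2, 2)))
        oracle = penalized_mle_oracle(S, 0.1, np.zeros((2, 2)))
        assert np.abs(O - oracle).max() < 1e-5

    def test_positive_definite_when_rank_deficient(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 20))  # n < p
        S = sample_covariance(X)
        O = ridge_precision(S, 0.125)
        assert np.linalg.eigvalsh(O).min() > 0

    def test_monotone_shrinkage_toward_target(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.integers(2, 6)
            S = random_spd(rng, p)
            T = random_spd(rng, p) + 0.2 * np.eye(p)
            dists = [
                np.linalg.norm(ridge_precision(S, lam, T) - T)
                for lam in np.logspace(-3, 4, 15)
            ]
            assert all(a >= b - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        S = random_spd(rng, 5)
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        O = ridge_precision(S, 0.3)
        O_perm = ridge_precision(P @ S @ P.T, 0.3)
        assert np.allclose(P @ O @ P.T, O_perm, atol=1e-10)

    def test_rejects_nonsymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            ridge_precision(np.array([[1.0, 0.5], [0.1, 1.0]]), 0.1)

    def test_rejects_nonpositive_penalty(self):
        with pytest.raises(ValueError):
            ridge_precision(np.eye(3), 0.0)


class TestPartialCorrelations:
    def test_diagonal_precision_gives_zero_partials(self):
        R = partial_correlations(np.diag([1.0, 2.0, 3.0]))
        assert np.array_equal(R, np.zeros((3, 3)))

    def test_two_by_two_hand_value(self):
        R = partial_correlations(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert R[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_regression_residual_correlation(self):
        # partial correlation of (0, 1) given 2 equals the correlation of
        # the residuals after regressing each on variable 2
        rng = np.random.default_rng(7)
        Sigma = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        omega = np.linalg.inv(Sigma)
        R = partial_correlations(omega)
        r01 = Sigma[0, 1] - Sigma[0, 2] * Sigma[1, 2] / Sigma[2, 2]
        v0 = Sigma[0, 0] - Sigma[0, 2] ** 2 / Sigma[2, 2]
        v1 = Sigma[1, 1] - Sigma[1, 2] ** 2 / Sigma[2, 2]
        assert R[0, 1] == pytest.approx(r01 / np.sqrt(v0 * v1), abs=1e-8)

    def test_rejects_indefinite_input(self):
        with pytest.raises(ValueError, match="positive definite"):
            partial_correlations(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLoocv:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 2))
        grid = np.array([0.1, 1.0])
        T = np.eye(2)
        res = loocv_select(X, grid, T=T)
        oracle = loocv_oracle(X, grid, T)
        assert np.abs(res.scores - oracle).max() < 1e-10

    def test_smoke_on_gaussian_data(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 5))
        grid = np.logspace(-2, 1, 8)
        a = loocv_select(X, grid)
        b = loocv_select(X, grid)
        assert np.isfinite(a.scores).all()
        assert a.selected == b.selected
        assert a.selected in grid

    def test_single_value_grid(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 3))
        res = loocv_select(X, [0.25])
        assert res.selected == 0.25

    def test_rejects_empty_or_negative_grid(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            loocv_select(X, [])
        with pytest.raises(ValueError):
            loocv_select(X, [-0.1, 0.5])


def test_fit_ggm_bundles_consistent_pieces():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((100, 6))
    fit = fit_ggm(X, lam=0.125)
    assert np.allclose(fit.S, sample_covariance(X), atol=1e-12)
    assert np.allclose(fit.partials, partial_correlations(fit.omega), atol=1e-12)
    assert np.allclose(fit.T, default_target(fit.S), atol=1e-12)
    assert np.abs(np.diag(fit.partials)).max() == 0.0
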