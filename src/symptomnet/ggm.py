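"""Ridge-regularized Gaussian graphical model estimation.

Given a rank-Gaussianized data matrix, the conditional-independence
structure of the variables is summarized by the precision matrix Omega
(inverse covariance): a zero off-diagonal entry means conditional
independence given all other variables, and the strength of a conditional
association is the partial correlation -omega_ij / sqrt(omega_ii omega_jj).

With p = 20 variables and n = 215 subjects the sample covariance is noisy,
so Omega is estimated with a Frobenius (ridge) penalty toward a target T:

    Omega_hat(lambda) = argmax  log det(Omega) - tr(S Omega)
                                - (lambda / 2) * ||Omega - T||_F^2

which has the exact closed form

    Omega_hat = { [lambda I + 1/4 (S - lambda T)^2]^{1/2}
                  + 1/2 (S - lambda T) }^{-1}

positive definite for every lambda > 0 even when S is singular (n < p).
The penalty is selected by leave-one-out cross-validation of the held-out
Gaussian negative log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def _check_symmetric(M: np.ndarray, name: str, atol: float = 1e-8) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=atol):
        raise ValueError(f"{name} must be symmetric")
    return M


def sample_covariance(X) -> np.ndarray:
    """Maximum-likelihood covariance S = (1/n) sum (x - xbar)(x - xbar)^T.

    Accepts an array or a TransformedMatrix. The 1/n convention matches
    the likelihood that the ridge estimator maximizes; on unit-variance
    input the diagonal of S is exactly 1.
    """
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        X = X.values
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need n >= 2 rows")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    return (S + S.T) / 2


def default_target(S: np.ndarray) -> np.ndarray:
    """Scaled-identity target alpha*I with alpha = p / trace(S).

    Rotation equivariant and approximately the identity for unit-variance
    input; defines the large-lambda limit of the estimator.
    """
    p = S.shape[0]
    return (p / np.trace(S)) * np.eye(p)


def ridge_precision(S: np.ndarray, lam: float, T: np.ndarray | None = None) -> np.ndarray:
    """Closed-form Frobenius-ridge precision estimate.

    Computed spectrally: with E = S - lambda*T = U diag(d) U', the estimate
    is U diag(1 / (sqrt(lambda + d^2/4) + d/2)) U', which is symmetric
    positive definite for all lambda > 0.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    S = _check_symmetric(S, "S")
    if T is None:
        T = default_target(S)
    T = _check_symmetric(T, "T")
    if T.shape != S.shape:
        raise ValueError("S and T must have the same dimension")

    E = S - lam * T
    d, U = np.linalg.eigh(E)
    inv_eigs = np.sqrt(lam + 0.25 * d**2) + 0.5 * d
    if (inv_eigs <= 0).any():  # impossible in exact arithmetic for lam > 0
        raise FloatingPointError("ridge precision estimate lost positive definiteness")
    omega = (U / inv_eigs) @ U.T
    return (omega + omega.T) / 2


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Scale a precision matrix to partial correlations.

    Off-diagonal entries are -omega_ij / sqrt(omega_ii * omega_jj); the
    diagonal is set to 0 by convention.
    """
    omega = _check_symmetric(omega, "omega")
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("omega must be positive definite")
    d = np.sqrt(np.diag(omega))
    R = -omega / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return (R + R.T) / 2


@dataclass
class PrecisionFit:
    """A fitted ridge GGM: covariance, penalty, target, precision, partials."""

    S: np.ndarray
    lam: float
    T: np.ndarray
    omega: np.ndarray
    partials: np.ndarray
    columns: list[str] | None = None


def fit_ggm(X, lam: float, T: np.ndarray | None = None) -> PrecisionFit:
    """Covariance -> ridge precision -> partial correlations, in one call."""
    columns = list(getattr(X, "columns", [])) or None
    S = sample_covariance(X)
    if T is None:
        T = default_target(S)
    omega = ridge_precision(S, lam, T)
    return PrecisionFit(S=S, lam=lam, T=T, omega=omega,
                        partials=partial_correlations(omega), columns=columns)


@dataclass
class CVResult:
    grid: np.ndarray
    scores: np.ndarray  # mean held-out negative log-likelihood per penalty
    selected: float


def _gaussian_nll(x: np.ndarray, mu: np.ndarray, omega: np.ndarray) -> float:
    r = x - mu
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    p = len(x)
    return 0.5 * (p * np.log(2 * np.pi) - logdet + r @ omega @ r)


def loocv_select(X, grid, T: np.ndarray | None = None) -> CVResult:
    """Leave-one-out cross-validation over a penalty grid.

    For each penalty and each held-out row, the model is refitted on the
    remaining n-1 rows (re-centered on their own mean) and scored by the
    Gaussian negative log-likelihood of the held-out row. The selected
    penalty minimizes the mean score; ties break toward the smaller
    penalty. Penalties with non-finite scores are excluded with a warning.
    """
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        X = X.values
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("LOOCV requires n >= 3")
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0 or (grid <= 0).any():
        raise ValueError("penalty grid must be nonempty and positive")

    # per-row leave-one-out means and covariances, shared across the grid
    mus = np.empty((n, p))
    covs = np.empty((n, p, p))
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        mus[i] = rest.mean(axis=0)
        Xc = rest - mus[i]
        Si = Xc.T @ Xc / (n - 1)
        covs[i] = (Si + Si.T) / 2

    scores = np.full(grid.size, np.inf)
    for g, lam in enumerate(grid):
        total = 0.0
        ok = True
        for i in range(n):
            Ti = T if T is not None else default_target(covs[i])
            omega = ridge_precision(covs[i], lam, Ti)
            nll = _gaussian_nll(X[i], mus[i], omega)
            if not np.isfinite(nll):
                ok = False
                break
            total += nll
        if ok:
            scores[g] = total / n
        else:
            logger.warning("loocv_select: non-finite score at lambda=%g, excluded", lam)

    finite = np.isfinite(scores)
    if not finite.any():
        raise RuntimeError("LOOCV produced no finite scores on the given grid")
    best = int(np.flatnonzero(finite)[np.argmin(scores[finite])])
    return CVResult(grid=grid, scores=scores, selected=float(grid[best]))
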