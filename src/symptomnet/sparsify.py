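"""Local-FDR edge selection for saturated partial-correlation networks.

The ridge fit yields a dense ("saturated") matrix of partial correlations;
most small entries are noise. Each off-diagonal pair is treated as a test
statistic on the variance-stabilized Fisher scale, z = atanh(r), and a
two-group empirical-Bayes model is fitted to the p(p-1)/2 statistics:

* the null component is a centered normal N(0, sigma0^2) whose scale is
  estimated by truncated maximum likelihood on the central statistics
  (|z| below the 75th percentile of |z|), so genuine edges in the tails
  do not inflate the null;
* the null proportion eta0 is the fraction of statistics in the central
  window divided by the null mass of that window, capped at 1;
* the marginal density f(z) is a Gaussian kernel density estimate
  (Silverman bandwidth).

The local false discovery rate lfdr(z) = min(1, eta0 * phi(z; 0, sigma0)
/ f(z)) is then the posterior probability that the pair is a null (absent)
edge; it is monotonized to be non-increasing in |z| so that thresholding
produces nested edge sets. An edge is retained when its posterior non-null
probability 1 - lfdr reaches the retention cut-off (default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gaussian_kde, norm


@dataclass
class LocalFdrFit:
    """Empirical-null two-group fit on Fisher-transformed statistics."""

    eta0: float
    sigma0: float
    kde: gaussian_kde

    def raw_lfdr(self, z: np.ndarray) -> np.ndarray:
        """Pointwise lfdr estimate, before monotonization."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        f = self.kde(z)
        f = np.maximum(f, 1e-300)
        return np.minimum(1.0, self.eta0 * norm.pdf(z, 0.0, self.sigma0) / f)

    def lfdr(self, z: np.ndarray) -> np.ndarray:
        """Monotonized lfdr: non-increasing in |z| via a running minimum
        taken outward from 0 over the evaluated set."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        raw = self.raw_lfdr(z)
        order = np.argsort(np.abs(z), kind="stable")
        mono = np.minimum.accumulate(raw[order])
        out = np.empty_like(raw)
        out[order] = mono
        return out


def fit_local_fdr(z_values: np.ndarray) -> LocalFdrFit:
    """Fit the empirical-null mixture to a vector of z statistics.

    Requires at least 10 statistics with some spread. Fails if the
    estimated null scale collapses below 1e-6 (degenerate input).
    """
    z = np.asarray(z_values, dtype=float).ravel()
    if z.size < 10:
        raise ValueError("need at least 10 test statistics for the empirical null")
    if np.ptp(z) == 0.0:
        raise ValueError("all z statistics identical; empirical null undefined")

    a = np.quantile(np.abs(z), 0.75)
    if a <= 0:
        raise ValueError("central |z| window has zero width; null scale collapsed")
    inside = z[np.abs(z) <= a]

    def neg_trunc_loglik(log_sigma: float) -> float:
        s = np.exp(log_sigma)
        window_mass = 2.0 * norm.cdf(a / s) - 1.0
        if window_mass <= 0:
            return np.inf
        return -(norm.logpdf(inside, 0.0, s).sum() - inside.size * np.log(window_mass))

    log_upper = float(np.log(10.0 * z.std() + 1e-8))
    res = minimize_scalar(
        neg_trunc_loglik,
        bounds=(np.log(1e-8), log_upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma0 = float(np.exp(res.x))
    if res.x > log_upper - 0.1:
        # the truncated likelihood is flat in sigma once the window looks
        # uniform (a truncated normal with sigma >> a is uniform on the
        # window), so a boundary solution means the scale is unidentified
        # by shape; fall back to central matching: pick sigma0 so the null
        # mass of the window equals the observed inside fraction
        frac = min(inside.size / z.size, 0.999)
        sigma0 = float(a / norm.ppf((1.0 + frac) / 2.0))
    if sigma0 < 1e-6:
        raise ValueError("estimated null scale collapsed below 1e-6")

    window_mass = 2.0 * norm.cdf(a / sigma0) - 1.0
    eta0 = min(1.0, (inside.size / z.size) / window_mass)

    kde = gaussian_kde(z, bw_method="silverman")
    return LocalFdrFit(eta0=eta0, sigma0=sigma0, kde=kde)


@dataclass(frozen=True)
class EdgeTest:
    """One node pair's partial correlation, Fisher z, lfdr and decision."""

    pair: tuple[str, str]
    r: float
    z: float
    lfdr: float
    retained: bool

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1

    @property
    def weight(self) -> float:
        return abs(self.r)


@dataclass
class SparseNetwork:
    """Edge-selection result: all pairwise tests plus the retained edge list."""

    nodes: list[str]
    tests: list[EdgeTest]
    cutoff: float
    fdr_fit: LocalFdrFit | None = field(default=None, repr=False)

    @property
    def edges(self) -> list[EdgeTest]:
        return [t for t in self.tests if t.retained]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, absolute: bool = True) -> np.ndarray:
        """Weighted adjacency over ``nodes`` (|r| by default, signed r otherwise)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)))
        for e in self.edges:
            i, j = idx[e.pair[0]], idx[e.pair[1]]
            w = abs(e.r) if absolute else e.r
            A[i, j] = A[j, i] = w
        return A

    def to_graph(self):
        """Retained edges as a networkx Graph with weight/sign/r/lfdr attributes."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for e in self.edges:
            G.add_edge(
                e.pair[0], e.pair[1],
                weight=float(abs(e.r)), r=float(e.r),
                sign=int(e.sign), lfdr=float(e.lfdr),
            )
        return G


def sparsify_network(
    partials: np.ndarray,
    cutoff: float = 0.80,
    nodes: list[str] | None = None,
) -> SparseNetwork:
    """Select edges whose posterior non-null probability reaches ``cutoff``.

    ``partials`` is the saturated symmetric partial-correlation matrix with
    zero diagonal. Each upper-triangle entry is Fisher-transformed, the
    empirical-null lfdr model is fitted to all p(p-1)/2 statistics, and a
    pair is retained when 1 - lfdr(z) >= cutoff. Retained edges keep the
    sign and magnitude of their partial correlation.
    """
    R = np.asarray(partials, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("partials must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("partials must be symmetric")
    if np.abs(np.diag(R)).max() > 1e-8:
        raise ValueError("partials must have zero diagonal")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    p = R.shape[0]
    if nodes is None:
        nodes = [f"V{j}" for j in range(p)]
    if len(nodes) != p:
        raise ValueError("node names do not match matrix dimension")

    iu, ju = np.triu_indices(p, k=1)
    r = np.clip(R[iu, ju], -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r)

    if np.ptp(z) == 0.0 and np.all(z == 0.0):
        # an exactly empty saturated matrix carries no evidence: no edges
        tests = [
            EdgeTest(pair=(nodes[i], nodes[j]), r=0.0, z=0.0, lfdr=1.0, retained=False)
            for i, j in zip(iu, ju)
        ]
        return SparseNetwork(nodes=list(nodes), tests=tests, cutoff=cutoff)

    fit = fit_local_fdr(z)
    lfdr = fit.lfdr(z)
    retained = (1.0 - lfdr) >= cutoff

    tests = [
        EdgeTest(
            pair=(nodes[i], nodes[j]),
            r=float(rv), z=float(zv), lfdr=float(lv), retained=bool(keep),
        )
        for i, j, rv, zv, lv, keep in zip(iu, ju, r, z, lfdr, retained)
    ]
    return SparseNetwork(nodes=list(nodes), tests=tests, cutoff=cutoff, fdr_fit=fit)
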