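"""Missingness screening, chained-equations imputation, nonparanormal transform.

The preprocessing chain turns a mixed-type table with missing cells into a
complete, rank-Gaussianized matrix suitable for Gaussian graphical
modelling:

1. :func:`screen_missingness` keeps only columns with strictly less than a
   threshold fraction (default 15%) of missing cells.
2. :func:`impute_chained` fills the remaining holes with a single
   chained-equations pass (regression imputation with Gaussian noise for
   continuous columns, predictive mean matching for ordinal/binary ones).
3. :func:`nonparanormal` maps each column through mid-ranks to standard
   normal quantiles, so only the rank (copula) information survives into
   the covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .schema import VariableSchema

logger = logging.getLogger(__name__)


@dataclass
class DataMatrix:
    """An N x P table with a missingness mask and bound variable schemas.

    ``frame`` holds the values with NaN marking missing cells; ``schema``
    is the ordered list of column schemas (same order as ``frame.columns``).
    """

    frame: pd.DataFrame
    schema: list[VariableSchema]

    def __post_init__(self) -> None:
        names = [s.name for s in self.schema]
        if list(self.frame.columns) != names:
            raise ValueError("frame columns do not match schema order")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean N x P array, True where the cell is missing."""
        return self.frame.isna().to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    def missing_fraction(self) -> pd.Series:
        return self.frame.isna().mean()

    def schema_for(self, name: str) -> VariableSchema:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def select_columns(self, names: Sequence[str]) -> "DataMatrix":
        keep = [s for s in self.schema if s.name in set(names)]
        return DataMatrix(self.frame[[s.name for s in keep]].copy(), keep)

    def take_rows(self, idx: np.ndarray) -> "DataMatrix":
        return DataMatrix(self.frame.iloc[idx].reset_index(drop=True), list(self.schema))


@dataclass
class TransformedMatrix:
    """Complete, rank-Gaussianized N x P matrix with unit column variances."""

    values: np.ndarray
    columns: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def screen_missingness(data: DataMatrix, threshold: float = 0.15) -> DataMatrix:
    """Drop columns whose missing fraction is >= ``threshold``.

    The inclusion rule is strict: a column with exactly 15% missing cells
    is excluded at the default threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frac = data.missing_fraction()
    keep = [c for c in data.columns if frac[c] < threshold]
    dropped = [c for c in data.columns if c not in keep]
    if dropped:
        logger.info("screen_missingness dropped %s (threshold %.3f)", dropped, threshold)
    if not keep:
        raise ValueError("all columns exceed the missingness threshold")
    return data.select_columns(keep)


def _pmm_draw(pred_obs, y_obs, pred_mis, rng, n_donors=5):
    """Predictive mean matching: for each target, draw one of the n_donors
    observed values nearest in linear predictor."""
    out = np.empty(len(pred_mis))
    k = min(n_donors, len(y_obs))
    for i, pm in enumerate(pred_mis):
        order = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
        out[i] = y_obs[order[rng.integers(k)]]
    return out


def impute_chained(
    data: DataMatrix,
    iterations: int = 10,
    seed: int | np.random.Generator = 0,
    n_donors: int = 5,
) -> DataMatrix:
    """Single stochastic chained-equations imputation.

    Missing cells are initialized with the column median (continuous) or
    mode (ordinal/binary), then the columns that contain missing values are
    revisited in schema order for ``iterations`` sweeps. Continuous columns
    are imputed by linear regression on all other columns plus a Gaussian
    residual draw (clipped to the declared range); ordinal and binary
    columns by predictive mean matching with ``n_donors`` donors nearest in
    the linear predictor, which guarantees valid category values.

    One completed dataset is returned per call; imputation uncertainty is
    meant to be propagated by re-running the whole pipeline (including this
    step) on subsamples, not by pooling multiple imputations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    X = data.values.copy()
    miss = data.mask
    if miss.all(axis=0).any():
        bad = [c for c, m in zip(data.columns, miss.all(axis=0)) if m]
        raise ValueError(f"columns entirely missing: {bad}")
    if not miss.any():
        return DataMatrix(data.frame.copy(), list(data.schema))

    cols_with_missing = [j for j in range(data.p) if miss[:, j].any()]

    # initialization: median / mode of observed values
    constant_cols = set()
    for j in cols_with_missing:
        s = data.schema[j]
        obs = X[~miss[:, j], j]
        if np.unique(obs).size == 1:
            logger.warning("impute_chained: column %s constant among observed values", s.name)
            X[miss[:, j], j] = obs[0]
            constant_cols.add(j)
        elif s.vtype == "continuous":
            X[miss[:, j], j] = np.median(obs)
        else:
            vals, counts = np.unique(obs, return_counts=True)
            X[miss[:, j], j] = vals[np.argmax(counts)]

    for _ in range(iterations):
        for j in cols_with_missing:
            if j in constant_cols:
                continue
            s = data.schema[j]
            mj = miss[:, j]
            others = np.delete(X, j, axis=1)
            design = np.column_stack([np.ones(data.n), others])
            beta, *_ = np.linalg.lstsq(design[~mj], X[~mj, j], rcond=None)
            pred = design @ beta
            if s.vtype == "continuous":
                resid = X[~mj, j] - pred[~mj]
                dof = max(int((~mj).sum()) - design.shape[1], 1)
                sigma = np.sqrt(max((resid**2).sum() / dof, 0.0))
                draw = pred[mj] + rng.normal(0.0, sigma, size=int(mj.sum()))
                X[mj, j] = np.clip(draw, s.range[0], s.range[1])
            else:
                X[mj, j] = _pmm_draw(pred[~mj], X[~mj, j], pred[mj], rng, n_donors)

    frame = pd.DataFrame(X, columns=data.columns)
    return DataMatrix(frame, list(data.schema))


def nonparanormal(data: DataMatrix | pd.DataFrame | np.ndarray,
                  columns: Sequence[str] | None = None) -> TransformedMatrix:
    """Rank-based Gaussianization (shrunken nonparanormal transform).

    Each column's values are replaced by standard normal quantiles of their
    mid-ranks, Phi^{-1}(r / (n + 1)) with average ranks for ties, then
    rescaled to unit sample variance (1/n convention). The map is strictly
    increasing on distinct values, so Spearman correlations — and therefore
    the fitted copula structure — are untouched while every marginal
    becomes Gaussian.
    """
    if isinstance(data, DataMatrix):
        if data.mask.any():
            raise ValueError("nonparanormal requires a complete matrix; impute first")
        X = data.values
        names = data.columns
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        names = list(data.columns)
    else:
        X = np.asarray(data, dtype=float)
        names = list(columns) if columns is not None else [f"V{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("nonparanormal requires n >= 3")
    if np.isnan(X).any():
        raise ValueError("nonparanormal requires a complete matrix")

    out = np.empty_like(X, dtype=float)
    for j in range(p):
        x = X[:, j]
        if np.ptp(x) == 0.0:
            raise ValueError(f"constant column {names[j]!r}: rank transform undefined")
        r = rankdata(x, method="average")
        z = norm.ppf(r / (n + 1))
        out[:, j] = z / z.std()  # 1/n convention; unit diagonal downstream
    return TransformedMatrix(out, list(names))
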