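"""Variable schemas for mixed-type questionnaire data.

A :class:`VariableSchema` declares, per column, everything the generator,
imputer and reporting layers need to agree on: the variable type
(continuous / ordinal / binary), the admissible instrument range, a
marginal distribution, and the expected missingness rate.

:func:`default_schema` returns the 20-variable set used throughout this
project: sociodemographic and clinical characteristics plus questionnaire
scores (awareness discrepancy, apathy, neuropsychiatric symptom subscales,
social participation, cognition, basic and instrumental activities of daily
living, quality of life) for a long-term-care population with severe
alcohol-related cognitive deficits, calibrated to the published sample
statistics (N = 215).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

VTYPES = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class VariableSchema:
    """Declared type, range, marginal and missingness for one column.

    Parameters
    ----------
    name : str
        Column identifier.
    vtype : {"continuous", "ordinal", "binary"}
    range : (lo, hi)
        Admissible values in instrument units. For ordinal/binary variables
        the categories are the integers ``lo .. hi``.
    mean, sd : float, optional
        Marginal mean / standard deviation (continuous variables; also kept
        as declared summary statistics for ordinal variables).
    probs : tuple of float, optional
        Category probabilities for ordinal/binary variables, ordered from
        ``lo`` to ``hi``; must sum to 1.
    missing_rate : float
        Expected fraction of missing cells, in [0, 1).
    """

    name: str
    vtype: str
    range: tuple[float, float]
    mean: float | None = None
    sd: float | None = None
    probs: tuple[float, ...] | None = field(default=None)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"{self.name}: unknown vtype {self.vtype!r}")
        lo, hi = self.range
        if not lo < hi:
            raise ValueError(f"{self.name}: range must satisfy lo < hi, got {self.range}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"{self.name}: missing_rate must lie in [0, 1)")
        if self.vtype == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: continuous variables need mean and sd > 0")
        else:
            if self.probs is None:
                raise ValueError(f"{self.name}: {self.vtype} variables need category probs")
            p = np.asarray(self.probs, dtype=float)
            n_cat = int(round(hi - lo)) + 1
            if len(p) != n_cat:
                raise ValueError(
                    f"{self.name}: {len(p)} probabilities for {n_cat} categories in {self.range}"
                )
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: category probabilities sum to {p.sum()}, not 1")
            if (p < 0).any():
                raise ValueError(f"{self.name}: negative category probability")
            if self.vtype == "binary" and n_cat != 2:
                raise ValueError(f"{self.name}: binary variables must have exactly 2 categories")

    @property
    def categories(self) -> np.ndarray:
        """Integer category values ``lo .. hi`` (ordinal/binary only)."""
        if self.vtype == "continuous":
            raise ValueError(f"{self.name}: continuous variable has no categories")
        lo, hi = self.range
        return np.arange(int(lo), int(hi) + 1, dtype=float)


def discretized_normal_probs(
    mean: float, sd: float, lo: int, hi: int
) -> tuple[float, ...]:
    """Category probabilities for integers lo..hi from a rounded normal.

    Each integer k receives the N(mean, sd) mass of (k - 1/2, k + 1/2],
    with the two end bins extended to cover the tails; used to turn a
    published mean/SD for a bounded integer score into a full marginal.
    """
    ks = np.arange(lo, hi + 1)
    upper = np.where(ks == hi, np.inf, ks + 0.5)
    lower = np.where(ks == lo, -np.inf, ks - 0.5)
    p = norm.cdf((upper - mean) / sd) - norm.cdf((lower - mean) / sd)
    p = p / p.sum()
    return tuple(float(x) for x in p)


def _binary(name: str, prevalence: float, missing_rate: float = 0.0) -> VariableSchema:
    return VariableSchema(
        name, "binary", (0, 1), mean=prevalence,
        probs=(1.0 - prevalence, prevalence), missing_rate=missing_rate,
    )


def _ordinal(
    name: str, lo: int, hi: int, mean: float, sd: float, missing_rate: float = 0.0
) -> VariableSchema:
    return VariableSchema(
        name, "ordinal", (lo, hi), mean=mean, sd=sd,
        probs=discretized_normal_probs(mean, sd, lo, hi), missing_rate=missing_rate,
    )


def default_schema() -> list[VariableSchema]:
    """The 20 study variables with published marginals and missingness.

    Continuous scores keep their instrument ranges (awareness discrepancy
    in [-120, 120], apathy in [10, 40], instrumental ADL in [0, 48],
    quality of life in [12, 84]); bounded integer scores are ordinal with
    a discretized-normal marginal matched to the published mean/SD; yes/no
    characteristics are binary with the published prevalence. Education is
    a 3-level category with the published level frequencies and 14.4%
    missingness — the only variable close to the 15% screening bound.
    """
    return [
        VariableSchema("Age", "continuous", (30, 95), mean=63.2, sd=7.9),
        _binary("Sex", 0.772),
        VariableSchema("LoS", "continuous", (0, 40), mean=6.7, sd=5.6),
        VariableSchema(
            "Edu", "ordinal", (1, 3), mean=1.42, sd=0.66,
            probs=(0.674, 0.234, 0.092), missing_rate=0.144,
        ),
        _binary("Single", 0.917, missing_rate=0.047),
        _binary("AP", 0.479),
        _binary("AD", 0.367),
        _binary("BZ", 0.307),
        VariableSchema("PCRS", "continuous", (-120, 120), mean=40.0, sd=20.0),
        VariableSchema("AES", "continuous", (10, 40), mean=25.3, sd=6.0,
                       missing_rate=0.009),
        _ordinal("NPI-Psy", 0, 6, 0.86, 1.5),
        _ordinal("NPI-Ag", 0, 9, 3.2, 2.6),
        _ordinal("NPI-Anx", 0, 3, 0.52, 1.0),
        _ordinal("NPI-Ap", 0, 3, 0.81, 1.0),
        _ordinal("NPI-Dep", 0, 3, 0.82, 1.1),
        _ordinal("RISE", 0, 6, 4.27, 1.8),
        _ordinal("CPS", 0, 6, 2.55, 1.6),
        _ordinal("ADL", 0, 6, 1.09, 1.2),
        VariableSchema("IADL", "continuous", (0, 48), mean=39.1, sd=8.3),
        VariableSchema("MANSA", "continuous", (12, 84), mean=61.0, sd=9.6,
                       missing_rate=0.014),
    ]


def continuous_schema(p: int, mean: float = 0.0, sd: float = 1.0) -> list[VariableSchema]:
    """A plain schema of ``p`` continuous N(mean, sd) variables, no missingness.

    Used for recovery experiments that isolate the graphical-model chain
    from discretization and imputation effects.
    """
    return [
        VariableSchema(f"V{j:02d}", "continuous", (mean - 8 * sd, mean + 8 * sd),
                       mean=mean, sd=sd)
        for j in range(p)
    ]


# --- serialization -----------------------------------------------------------

def schema_to_dict(schema: Sequence[VariableSchema]) -> list[dict]:
    out = []
    for s in schema:
        d = {
            "name": s.name,
            "vtype": s.vtype,
            "range": [float(s.range[0]), float(s.range[1])],
            "missing_rate": float(s.missing_rate),
        }
        if s.mean is not None:
            d["mean"] = float(s.mean)
        if s.sd is not None:
            d["sd"] = float(s.sd)
        if s.probs is not None:
            d["probs"] = [float(x) for x in s.probs]
        out.append(d)
    return out


def schema_from_dict(items: Sequence[dict]) -> list[VariableSchema]:
    return [
        VariableSchema(
            name=d["name"], vtype=d["vtype"],
            range=(d["range"][0], d["range"][1]),
            mean=d.get("mean"), sd=d.get("sd"),
            probs=tuple(d["probs"]) if "probs" in d else None,
            missing_rate=d.get("missing_rate", 0.0),
        )
        for d in items
    ]


def write_schema(schema: Sequence[VariableSchema], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"variables": schema_to_dict(schema)}, fh, sort_keys=False)


def read_schema(path) -> list[VariableSchema]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return schema_from_dict(payload["variables"])
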