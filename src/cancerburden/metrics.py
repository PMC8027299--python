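"""Headline burden metrics: direct age-standardization, annual percent
change, years of life lost, and the mortality-to-incidence ratio."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LifeTable

__all__ = [
    "StandardPopulation",
    "TrendSeries",
    "age_standardize",
    "compute_apc",
    "geometric_series",
    "compute_yll",
    "compute_mir",
]


@dataclass
class StandardPopulation:
    """Age weights of the reference population (direct standardization)."""

    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("standard-population weights must be nonnegative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("standard-population weights must sum to a positive total")
        self.weights = self.weights / total

    @classmethod
    def from_counts(cls, counts: np.ndarray, provenance: str = "") -> "StandardPopulation":
        return cls(weights=np.asarray(counts, dtype=float), provenance=provenance)


@dataclass
class TrendSeries:
    """Ordered (year, value) pairs with positive values."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values differ in length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")


def age_standardize(age_rates: np.ndarray, std: StandardPopulation) -> float:
    """Directly standardized rate: sum of age weights times age rates."""
    rates = np.asarray(age_rates, dtype=float)
    if rates.shape != std.weights.shape:
        raise ValueError(
            f"rate vector length {rates.shape} does not match weights {std.weights.shape}"
        )
    return float(std.weights @ rates)


def compute_apc(series: TrendSeries) -> float:
    """Annual percent change from the log-linear trend.

    Ordinary least squares of ln(value) on year; APC = 100 (exp(beta) - 1).
    Requires at least 3 points, all positive.
    """
    if len(series.years) < 3:
        raise ValueError("need at least 3 points for APC")
    bad = np.nonzero(series.values <= 0)[0]
    if len(bad):
        raise ValueError(f"nonpositive value in year {int(series.years[bad[0]])}")
    beta = np.polyfit(series.years, np.log(series.values), 1)[0]
    return float(100.0 * np.expm1(beta))


def geometric_series(
    year0: int, value0: float, year1: int, value1: float
) -> TrendSeries:
    """Exact geometric interpolation between two printed endpoints.

    The log-linear APC of this series equals the endpoint growth rate, so it
    reproduces an APC reported alongside the two endpoint rates.
    """
    if value0 <= 0 or value1 <= 0:
        raise ValueError("endpoints must be positive")
    years = np.arange(year0, year1 + 1)
    frac = (years - year0) / (year1 - year0)
    values = value0 * (value1 / value0) ** frac
    return TrendSeries(years=years, values=values)


def compute_yll(
    deaths: np.ndarray,
    life: LifeTable,
    population: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Years of life lost per age group: deaths times remaining expectancy.

    No discounting or age-weighting.  When ``population`` is given, also
    returns the YLL rate per 100,000.
    """
    deaths = np.asarray(deaths, dtype=float)
    le = np.asarray(life.expectancy, dtype=float)
    if deaths.shape != le.shape:
        raise ValueError("life table does not cover the death age groups")
    if np.any((deaths > 0) & ~np.isfinite(le)):
        raise ValueError("missing life expectancy for an age group with deaths")
    yll = deaths * le
    if population is None:
        return yll, None
    population = np.asarray(population, dtype=float)
    rate = np.where(population > 0, yll / population * 1e5, 0.0)
    return yll, rate


def compute_mir(asdr: float, asir: float) -> float:
    """Mortality-to-incidence ratio of two (age-standardized) rates.

    Returns NaN (flagged missing) when the incidence rate is nonpositive.
    """
    if asir <= 0:
        return float("nan")
    return float(asdr / asir)
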