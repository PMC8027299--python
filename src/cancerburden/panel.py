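"""Stratum-level containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["PanelCounts", "RateSurface"]


@dataclass
class PanelCounts:
    """Event counts and person-years on the province x age-group x year grid.

    Counts may be fractional after completeness correction or cause-fraction
    allocation.
    """

    events: np.ndarray  # (P, A, Y)
    person_years: np.ndarray  # (P, A, Y)
    provinces: list[int]
    age_groups: list[str]
    years: list[int]

    def __post_init__(self) -> None:
        if self.events.shape != self.person_years.shape:
            raise ValueError("events and person-years grids differ in shape")
        expect = (len(self.provinces), len(self.age_groups), len(self.years))
        if self.events.shape != expect:
            raise ValueError(f"grid shape {self.events.shape} != labels {expect}")
        if np.any(self.events < 0) or np.any(self.person_years < 0):
            raise ValueError("negative counts or person-years")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.events.shape

    def rates(self, continuity: float = 0.0) -> np.ndarray:
        """Observed rate per 100,000; zero-event strata optionally get a
        0.5-event continuity correction when ``continuity`` is 0.5."""
        ev = self.events + continuity * (self.events == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.person_years > 0, ev / self.person_years * 1e5, 0.0)
        return r

    def with_events(self, events: np.ndarray) -> "PanelCounts":
        return replace(self, events=events)

    def to_frame(self, value_name: str = "events") -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.provinces, self.age_groups, self.years],
            names=["province", "age_group", "year"],
        )
        return pd.DataFrame(
            {
                value_name: self.events.reshape(-1),
                "person_years": self.person_years.reshape(-1),
            },
            index=idx,
        ).reset_index()


@dataclass
class RateSurface:
    """Point rates with draw-based 95% uncertainty bounds, per 100,000."""

    rate: np.ndarray  # (P, A, Y)
    lower: np.ndarray
    upper: np.ndarray
    provinces: list[int]
    age_groups: list[str]
    years: list[int]

    def __post_init__(self) -> None:
        for name, arr in (("rate", self.rate), ("lower", self.lower), ("upper", self.upper)):
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and nonnegative")
        if np.any(self.lower > self.rate + 1e-12) or np.any(self.upper < self.rate - 1e-12):
            raise ValueError("bounds must bracket the point estimate")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.provinces, self.age_groups, self.years],
            names=["province", "age_group", "year"],
        )
        return pd.DataFrame(
            {
                "rate": self.rate.reshape(-1),
                "lower": self.lower.reshape(-1),
                "upper": self.upper.reshape(-1),
            },
            index=idx,
        ).reset_index()
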