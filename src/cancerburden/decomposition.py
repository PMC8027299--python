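"""Decomposition of the change in new-case counts into population growth,
population aging, and age-specific rate change.

Two hypothetical populations split the change between a base and a final
year: H1 applies base-year age-specific rates and base-year age structure
to the final-year population total (growth = H1 - base cases); H2 applies
base-year rates to the final-year population and structure (aging = H2 -
H1); the remainder against observed final-year cases is attributed to rate
change.  The three components sum to the total change exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["DecompositionResult", "decompose_change"]


@dataclass
class DecompositionResult:
    cases_base: float
    cases_final: float
    h1: float
    h2: float
    delta_growth: float
    delta_aging: float
    delta_rate: float
    pct_growth: float
    pct_aging: float
    pct_rate: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def decompose_change(
    rates_base: np.ndarray,
    pop_base: np.ndarray,
    pop_final: np.ndarray,
    cases_final: float,
) -> DecompositionResult:
    """Split cases_final - cases_base into growth, aging and rate components.

    ``rates_base`` are base-year age-specific rates per 100,000;
    populations are age-aligned person counts.  ``cases_final`` is the
    observed (or estimated) final-year case count, not recomputed from
    final-year rates.
    """
    rates_base = np.asarray(rates_base, dtype=float)
    pop_base = np.asarray(pop_base, dtype=float)
    pop_final = np.asarray(pop_final, dtype=float)
    if not (rates_base.shape == pop_base.shape == pop_final.shape):
        raise ValueError("age grids of rates and populations do not match")
    tot_base = pop_base.sum()
    tot_final = pop_final.sum()
    if tot_base <= 0 or tot_final <= 0:
        raise ValueError("total population must be positive")

    cases_base = float(rates_base @ pop_base / 1e5)
    struct_base = pop_base / tot_base
    h1 = float((rates_base @ struct_base) * tot_final / 1e5)
    h2 = float(rates_base @ pop_final / 1e5)
    d_growth = h1 - cases_base
    d_aging = h2 - h1
    d_rate = float(cases_final) - h2
    if cases_base == 0:
        raise ValueError("base-year cases are zero; percent change undefined")
    pct = 100.0 / cases_base
    return DecompositionResult(
        cases_base=cases_base,
        cases_final=float(cases_final),
        h1=h1,
        h2=h2,
        delta_growth=d_growth,
        delta_aging=d_aging,
        delta_rate=d_rate,
        pct_growth=d_growth * pct,
        pct_aging=d_aging * pct,
        pct_rate=d_rate * pct,
    )
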