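"""Synthetic cancer/death-registry generator with known ground truth.

Real national registries (cancer registration, death registration, and a
second partially overlapping capture source used for completeness
estimation) are confidential.  This module emulates them: a latent
log-linear incidence/mortality rate surface over province x age-group x
year, Poisson event counts given population, per-source under-registration,
duplicate entries and missing demographic fields.  Every record carries a
hidden ``truth_link`` so downstream corrections can be scored against the
generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUP_LABELS",
    "age_group_labels",
    "age_group_midpoints",
    "SimulationConfig",
    "ObservationConfig",
    "TruthSurface",
    "PopulationTable",
    "LifeTable",
    "CovariateTable",
    "SimulatedRegistries",
    "make_geography",
    "simulate_truth",
    "make_population",
    "make_life_table",
    "make_covariates",
    "simulate_registry",
]

MISSING = ""  # encoding of a missing field in CSV output


def age_group_labels(n_groups: int = 15, start: int = 15, width: int = 5) -> list[str]:
    """5-year age-group labels, last group open-ended (e.g. ``85+``)."""
    labels = [
        f"{start + i * width}-{start + (i + 1) * width - 1}" for i in range(n_groups - 1)
    ]
    labels.append(f"{start + (n_groups - 1) * width}+")
    return labels


AGE_GROUP_LABELS = age_group_labels()


def age_group_midpoints(n_groups: int = 15, start: int = 15, width: int = 5) -> np.ndarray:
    mids = start + width * np.arange(n_groups) + (width - 1) / 2.0
    return mids.astype(float)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Parameters of the latent rate surface and demography.

    Rates are per 100,000 person-years.  ``annual_change`` is the constant
    multiplicative trend ``rate(y+1)/rate(y) - 1`` shared by all strata;
    ``slope_sd`` adds spatially correlated per-province deviations from it,
    so provinces can trend apart (these deviations are deliberately outside
    the stage-1 model and are what residual smoothing must recover).
    """

    n_provinces: int = 31
    n_age_groups: int = 15
    age_start: int = 15
    year_start: int = 1990
    year_end: int = 2016
    # incidence at the youngest group and log-linear rise with age, chosen to
    # span roughly 4 to 400 per 100,000 across the 15 groups as female breast
    # cancer does at the end of the study period
    base_rate_young: float = 4.0
    age_log_slope: float = 0.31  # per 5-year group on the log scale
    annual_change: float = 0.045
    slope_sd: float = 0.0
    province_sd: float = 0.25
    spatial_scale: float = 0.0
    mortality_fraction: float = 0.35  # deaths per case at steady state, <1
    # demography
    population_base: float = 1_200_000.0  # mean female province population
    population_growth: float = 0.013  # annual
    age_pyramid_decay: float = 0.18  # per group, young-heavy pyramid

    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def age_labels(self) -> list[str]:
        return age_group_labels(self.n_age_groups, self.age_start)

    def age_profile(self) -> np.ndarray:
        """Baseline incidence per 100,000 by age group."""
        return self.base_rate_young * np.exp(
            self.age_log_slope * np.arange(self.n_age_groups)
        )

    def validate(self) -> None:
        vals = [
            self.base_rate_young,
            self.age_log_slope,
            self.annual_change,
            self.slope_sd,
            self.province_sd,
            self.spatial_scale,
            self.mortality_fraction,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("simulation config contains non-finite values")
        if not (0 < self.mortality_fraction < 1):
            raise ValueError("mortality_fraction must lie in (0, 1)")
        if self.annual_change <= -1:
            raise ValueError("annual_change must exceed -1")


@dataclass
class ObservationConfig:
    """How the registries observe true events.

    ``pi_*`` are per-source registration (capture) probabilities in (0, 1];
    capture in the cancer registry and in the reference source are
    conditionally independent given the true case.  Missingness is applied
    per field after registration and duplication.
    """

    pi_crs: float = 0.85
    pi_drs: float = 0.90
    pi_ssocr: float = 0.60
    missing_age: float = 0.05
    missing_sex: float = 0.03
    missing_province: float = 0.04
    duplicate_prob: float = 0.05
    causes: tuple[str, ...] = ("breast",)
    cause_probs: tuple[float, ...] = (1.0,)

    def validate(self) -> None:
        for name in ("pi_crs", "pi_drs", "pi_ssocr"):
            p = getattr(self, name)
            if not (0 < p <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {p}")
        for name in ("missing_age", "missing_sex", "missing_province", "duplicate_prob"):
            p = getattr(self, name)
            if not (0 <= p < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {p}")
        if len(self.causes) != len(self.cause_probs):
            raise ValueError("causes and cause_probs must have equal length")
        if abs(sum(self.cause_probs) - 1.0) > 1e-9:
            raise ValueError("cause_probs must sum to 1")


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class TruthSurface:
    """Latent rates per 100,000 on the (province, age-group, year) grid."""

    incidence_rate: np.ndarray  # (P, A, Y)
    mortality_rate: np.ndarray  # (P, A, Y)
    config: SimulationConfig
    province_effects: np.ndarray  # (P,) log scale, intercept + spatial
    slopes: np.ndarray  # (P,) annual log slope per province

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.incidence_rate.shape

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.incidence_rate)):
            raise ValueError("incidence surface contains non-finite rates")
        if np.any(self.incidence_rate < 0) or np.any(self.mortality_rate < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(self.mortality_rate > self.incidence_rate + 1e-9):
            raise ValueError("mortality rate exceeds incidence rate in some stratum")


@dataclass
class PopulationTable:
    """Female population counts on the (province, age-group, year) grid."""

    population: np.ndarray  # (P, A, Y) integer
    provinces: list[int]
    age_groups: list[str]
    years: list[int]

    def __post_init__(self) -> None:
        if np.any(self.population < 0):
            raise ValueError("population cells must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        P, A, Y = self.population.shape
        idx = pd.MultiIndex.from_product(
            [self.provinces, self.age_groups, self.years],
            names=["province", "age_group", "year"],
        )
        return pd.DataFrame(
            {"population": self.population.reshape(-1)}, index=idx
        ).reset_index()


@dataclass
class LifeTable:
    """Remaining life expectancy (years) by age group; strictly decreasing."""

    expectancy: np.ndarray  # (A,)
    age_groups: list[str]

    def __post_init__(self) -> None:
        if np.any(self.expectancy <= 0):
            raise ValueError("life expectancy must be positive")
        if np.any(np.diff(self.expectancy) >= 0):
            raise ValueError("life expectancy must decrease strictly with age")


@dataclass
class CovariateTable:
    """Province-year covariates: wealth index, schooling years, urbanization."""

    frame: pd.DataFrame  # columns province, year, wealth, schooling_years, urbanization

    def __post_init__(self) -> None:
        f = self.frame
        if f[["wealth", "schooling_years", "urbanization"]].isna().any().any():
            raise ValueError("covariate table has missing cells")
        if ((f["urbanization"] < 0) | (f["urbanization"] > 1)).any():
            raise ValueError("urbanization must lie in [0, 1]")


@dataclass
class SimulatedRegistries:
    """The three observed tables plus the hidden truth for scoring."""

    crs: pd.DataFrame
    drs: pd.DataFrame
    ssocr: pd.DataFrame
    true_case_counts: np.ndarray  # (P, A, Y)
    true_death_counts: np.ndarray  # (P, A, Y)


REGISTRY_COLUMNS = [
    "record_id",
    "source",
    "cause",
    "age",
    "sex",
    "province",
    "year",
    "truth_link",
]


# ---------------------------------------------------------------------------
# generators


def make_geography(n_provinces: int, seed: int) -> np.ndarray:
    """Random connected province adjacency (symmetric binary, zero diagonal).

    A uniform random spanning tree guarantees connectivity; extra edges are
    then switched on independently to give provinces 2-4 neighbours on
    average, which is about what a real contiguous subdivision map has.
    """
    if n_provinces < 2:
        raise ValueError("need at least 2 provinces")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_provinces, n_provinces), dtype=int)
    order = rng.permutation(n_provinces)
    for i in range(1, n_provinces):
        j = order[rng.integers(0, i)]
        adj[order[i], j] = adj[j, order[i]] = 1
    extra = rng.random((n_provinces, n_provinces)) < 2.0 / n_provinces
    extra = np.triu(extra, 1)
    adj |= extra | extra.T
    np.fill_diagonal(adj, 0)
    assert nx.is_connected(nx.from_numpy_array(adj))
    return adj


def _spatial_effect(adjacency: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """One spatially correlated Gaussian effect per province.

    White noise is propagated through a one-step smoothed adjacency kernel
    (self weight plus equal neighbour shares), then standardized so `scale`
    is the marginal SD.
    """
    P = adjacency.shape[0]
    if scale == 0:
        return np.zeros(P)
    deg = adjacency.sum(axis=1).clip(min=1)
    kernel = 0.5 * np.eye(P) + 0.5 * adjacency / deg[:, None]
    z = rng.standard_normal(P)
    eff = kernel @ z
    row_sd = np.sqrt((kernel**2).sum(axis=1))
    return scale * eff / row_sd


def simulate_truth(
    config: SimulationConfig, adjacency: np.ndarray, seed: int
) -> TruthSurface:
    """Draw the latent rate surface.

    log incidence = log(age profile) + province effect + slope_p * (year - y0),
    with the province effect the sum of an iid intercept (``province_sd``)
    and a spatially correlated term (``spatial_scale``), and the slope
    ``log(1 + annual_change)`` plus a spatially correlated deviation
    (``slope_sd``).  Mortality is a fixed fraction of incidence, so deaths
    never outpace cases.
    """
    config.validate()
    P = config.n_provinces
    if adjacency.shape != (P, P):
        raise ValueError("adjacency shape does not match n_provinces")
    rng = np.random.default_rng(seed)
    intercepts = config.province_sd * rng.standard_normal(P) if config.province_sd else np.zeros(P)
    spatial = _spatial_effect(adjacency, config.spatial_scale, rng)
    slope_dev = _spatial_effect(adjacency, config.slope_sd, rng) if config.slope_sd else np.zeros(P)
    slopes = np.log1p(config.annual_change) + slope_dev

    years = config.years()
    t = years - years[0]
    log_age = np.log(config.age_profile())  # (A,)
    log_rate = (
        log_age[None, :, None]
        + (intercepts + spatial)[:, None, None]
        + slopes[:, None, None] * t[None, None, :]
    )
    inc = np.exp(log_rate)
    mort = config.mortality_fraction * inc
    return TruthSurface(
        incidence_rate=inc,
        mortality_rate=mort,
        config=config,
        province_effects=intercepts + spatial,
        slopes=slopes,
    )


def make_population(config: SimulationConfig, seed: int) -> PopulationTable:
    """Female population on the grid: lognormal province sizes, a young-heavy
    age pyramid decaying geometrically, and steady annual growth."""
    rng = np.random.default_rng(seed)
    P, A = config.n_provinces, config.n_age_groups
    years = config.years()
    sizes = config.population_base * np.exp(0.6 * rng.standard_normal(P))
    pyramid = np.exp(-config.age_pyramid_decay * np.arange(A))
    pyramid /= pyramid.sum()
    growth = (1 + config.population_growth) ** (years - years[0])
    pop = sizes[:, None, None] * pyramid[None, :, None] * growth[None, None, :]
    return PopulationTable(
        population=np.round(pop).astype(np.int64),
        provinces=list(range(1, P + 1)),
        age_groups=config.age_labels(),
        years=list(years),
    )


def make_life_table(config: SimulationConfig) -> LifeTable:
    """Remaining life expectancy by age group (Gompertz-like decline).

    Roughly 66 years remaining at ages 15-19 falling to ~4.5 at 85+,
    comparable to a modern middle-income female life table.
    """
    mids = age_group_midpoints(config.n_age_groups, config.age_start)
    le = 66.0 * np.exp(-0.0385 * (mids - 17.5))
    return LifeTable(expectancy=le, age_groups=config.age_labels())


def make_covariates(config: SimulationConfig, seed: int) -> CovariateTable:
    """Province-year wealth, schooling and urbanization with mild trends."""
    rng = np.random.default_rng(seed)
    P = config.n_provinces
    years = config.years()
    t = (years - years[0]) / max(len(years) - 1, 1)
    prov_wealth = rng.normal(0, 0.8, P)
    prov_school = rng.normal(6.5, 1.2, P)
    prov_urban = rng.normal(0.0, 0.7, P)
    rows = []
    for i in range(P):
        wealth = prov_wealth[i] + 1.1 * t
        school = prov_school[i] + 3.0 * t
        urban = 1 / (1 + np.exp(-(prov_urban[i] + 1.4 * t - 0.2)))
        for j, y in enumerate(years):
            rows.append((i + 1, int(y), wealth[j], school[j], urban[j]))
    frame = pd.DataFrame(
        rows, columns=["province", "year", "wealth", "schooling_years", "urbanization"]
    )
    return CovariateTable(frame=frame)


def _draw_ages(
    group_idx: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Single-year ages uniform within the 5-year group (85+ spans 10 years)."""
    lo = config.age_start + 5 * group_idx
    width = np.where(group_idx == config.n_age_groups - 1, 10, 5)
    return lo + rng.integers(0, width)


def simulate_registry(
    truth: TruthSurface,
    population: PopulationTable,
    obs_config: ObservationConfig,
    seed: int,
) -> SimulatedRegistries:
    """Observe the truth through three imperfect registries.

    True stratum counts are Poisson(rate x population / 100,000).  Each true
    case enters the cancer registry (CRS) with probability ``pi_crs`` and the
    reference source (SSOCR) independently with ``pi_ssocr``; deaths enter
    the death registry (DRS) with ``pi_drs``.  Duplicates re-draw a record id
    but share the truth link; missingness hits fields afterwards.
    """
    obs_config.validate()
    rng = np.random.default_rng(seed)
    cfg = truth.config
    P, A, Y = truth.shape
    pop = population.population.astype(float)
    mean_cases = truth.incidence_rate * pop / 1e5
    mean_deaths = truth.mortality_rate * pop / 1e5
    n_cases = rng.poisson(mean_cases)
    n_deaths = rng.poisson(mean_deaths)

    def _events(counts: np.ndarray, prefix: str) -> pd.DataFrame:
        p_idx, a_idx, y_idx = np.nonzero(counts)
        reps = counts[p_idx, a_idx, y_idx]
        p_idx = np.repeat(p_idx, reps)
        a_idx = np.repeat(a_idx, reps)
        y_idx = np.repeat(y_idx, reps)
        n = len(p_idx)
        causes = rng.choice(len(obs_config.causes), size=n, p=obs_config.cause_probs)
        return pd.DataFrame(
            {
                "truth_link": [f"{prefix}{k}" for k in range(n)],
                "cause": np.asarray(obs_config.causes)[causes],
                "age": _draw_ages(a_idx, cfg, rng),
                "province": p_idx + 1,
                "year": cfg.year_start + y_idx,
            }
        )

    cases = _events(n_cases, "C")
    deaths = _events(n_deaths, "D")

    def _capture(events: pd.DataFrame, pi: float, source: str) -> pd.DataFrame:
        keep = events[rng.random(len(events)) < pi].copy()
        # planted duplicates: extra rows sharing the truth link
        if obs_config.duplicate_prob > 0 and len(keep):
            dup = keep[rng.random(len(keep)) < obs_config.duplicate_prob]
            keep = pd.concat([keep, dup], ignore_index=True)
        keep = keep.reset_index(drop=True)
        out = pd.DataFrame(
            {
                "record_id": [f"{source}-{k:07d}" for k in range(len(keep))],
                "source": source,
                "cause": keep["cause"].to_numpy(),
                "age": keep["age"].astype("object"),
                "sex": np.array(["female"] * len(keep), dtype=object),
                "province": keep["province"].astype("object"),
                "year": keep["year"].to_numpy(),
                "truth_link": keep["truth_link"].to_numpy(),
            }
        )
        for col, p in (
            ("age", obs_config.missing_age),
            ("sex", obs_config.missing_sex),
            ("province", obs_config.missing_province),
        ):
            if p > 0 and len(out):
                mask = rng.random(len(out)) < p
                out.loc[mask, col] = pd.NA
        return out[REGISTRY_COLUMNS]

    crs = _capture(cases, obs_config.pi_crs, "CRS")
    ssocr = _capture(cases, obs_config.pi_ssocr, "SSOCR")
    drs = _capture(deaths, obs_config.pi_drs, "DRS")
    return SimulatedRegistries(
        crs=crs,
        drs=drs,
        ssocr=ssocr,
        true_case_counts=n_cases,
        true_death_counts=n_deaths,
    )


# ---------------------------------------------------------------------------
# CSV round trip


def write_registry_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep=MISSING, columns=REGISTRY_COLUMNS)


def read_registry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"record_id": str, "source": str, "cause": str, "sex": object},
        keep_default_na=False,
        na_values=[MISSING],
    )
    for col in ("age", "province"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("object")
        df.loc[df[col].isna(), col] = pd.NA
    return df[[c for c in REGISTRY_COLUMNS if c in df.columns]]
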