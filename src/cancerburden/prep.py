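"""Registry preparation: deduplication, hot-deck multiple imputation,
two-source completeness estimation and correction, province remapping, and
aggregation to stratum counts.

The completeness estimator treats the reference capture source as an
enumeration standard: in a stratum with n2 reference captures of which m are
also found in the primary registry, primary completeness is m / n2.  A
symmetric Chandra Sekar-Deming (Lincoln-Petersen) variant is available
behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelCounts
from .synthetic import PopulationTable

__all__ = [
    "ProvinceMap",
    "deduplicate",
    "impute_missing",
    "estimate_completeness",
    "correct_counts",
    "remap_provinces",
    "aggregate_counts",
]

log = logging.getLogger(__name__)

IMPUTABLE_FIELDS = ("age", "sex", "province")
MATCH_KEYS = ["source", "cause", "age", "sex", "province", "year"]


@dataclass
class ProvinceMap:
    """Legacy district/province code -> current province id (1..P)."""

    mapping: dict[int, int]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty province map")


def _normalize_id(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.lower()


def deduplicate(
    table: pd.DataFrame, by: tuple[str, ...] = ("record_id", "fields")
) -> pd.DataFrame:
    """Drop duplicate rows, keeping the first occurrence.

    Two rules, applied in order when selected: rows whose record ids are
    equal after whitespace/case normalization, and rows identical on all of
    (source, cause, age, sex, province, year).  The number of removals is
    logged.  Missing fields compare equal to each other, so two fully
    anonymous rows collapse; key-based matching is therefore meant for
    registries where demographics are close to identifying.
    """
    out = table
    removed = 0
    if "record_id" in by:
        keep = ~_normalize_id(out["record_id"]).duplicated()
        removed += int((~keep).sum())
        out = out[keep]
    if "fields" in by:
        keep = ~out[MATCH_KEYS].duplicated()
        removed += int((~keep).sum())
        out = out[keep]
    if removed:
        log.info("deduplicate: removed %d of %d rows", removed, len(table))
    return out.reset_index(drop=True)


def _donor_pools(table: pd.DataFrame) -> pd.DataFrame:
    complete = table.dropna(subset=list(IMPUTABLE_FIELDS))
    return complete


def impute_missing(table: pd.DataFrame, m: int, seed: int) -> list[pd.DataFrame]:
    """Hot-deck multiple imputation of missing age/sex/province.

    Each missing cell is filled with a value drawn from the empirical
    distribution of complete records in the same source x year stratum,
    falling back to the same source across all years.  Returns ``m``
    completed copies; deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    complete = _donor_pools(table)
    out: list[pd.DataFrame] = []
    missing_any = table[list(IMPUTABLE_FIELDS)].isna().any(axis=1)
    for _ in range(m):
        filled = table.copy()
        for ridx in table.index[missing_any]:
            row = table.loc[ridx]
            donors = complete[
                (complete["source"] == row["source"]) & (complete["year"] == row["year"])
            ]
            if donors.empty:
                donors = complete[complete["source"] == row["source"]]
            if donors.empty:
                raise ValueError(
                    f"no complete donor records for source={row['source']!r}, "
                    f"year={row['year']!r}"
                )
            for field in IMPUTABLE_FIELDS:
                if pd.isna(row[field]):
                    pick = donors[field].iloc[rng.integers(0, len(donors))]
                    filled.at[ridx, field] = pick
        out.append(filled)
    return out


def estimate_completeness(
    primary: pd.DataFrame,
    reference: pd.DataFrame,
    level: str = "province_year",
    key: str = "record_id",
    symmetric: bool = False,
) -> pd.DataFrame:
    """Two-source capture-recapture completeness of the primary registry.

    Per stratum (province x year by default, or year only): n1 = primary
    captures, n2 = reference captures, m = events captured by both (matched
    on the normalized linkage key).  Completeness of the primary source is
    m / n2, the reference being treated as the enumeration standard.  For the
    primary source's coverage the symmetric Chandra Sekar-Deming estimator
    n1 / N with N = n1 n2 / m reduces to the same m / n2; ``symmetric=True``
    additionally reports the implied total N per stratum.  Strata with
    n2 = 0 are flagged, never silently set to 1.

    Returns a frame ``province,year,completeness,n1,n2,m,flagged`` (the
    province column is omitted at level="year").
    """
    if level not in ("province_year", "year"):
        raise ValueError("level must be 'province_year' or 'year'")
    strata = ["province", "year"] if level == "province_year" else ["year"]
    tables = []
    for t, name in ((primary, "primary"), (reference, "reference")):
        n_bad = int(t[strata].isna().any(axis=1).sum())
        if n_bad:
            log.warning(
                "estimate_completeness: dropping %d %s rows with missing stratum fields",
                n_bad,
                name,
            )
            t = t.dropna(subset=strata)
        tables.append(t)
    primary, reference = tables

    def _keyed(t: pd.DataFrame) -> pd.DataFrame:
        out = t[strata].copy()
        out["_key"] = _normalize_id(t[key])
        return out

    p = _keyed(primary)
    r = _keyed(reference)
    p_sets = p.groupby(strata)["_key"].agg(set)
    r_sets = r.groupby(strata)["_key"].agg(set)
    idx = sorted(set(p_sets.index) | set(r_sets.index))
    rows = []
    for s in idx:
        pk = p_sets.get(s, set())
        rk = r_sets.get(s, set())
        n1, n2, mm = len(pk), len(rk), len(pk & rk)
        if mm > min(n1, n2):
            raise ValueError(f"matched count exceeds a source count in stratum {s}")
        flagged = n2 == 0
        comp = np.nan if flagged else mm / n2
        chand_n = np.nan
        if symmetric and mm > 0:
            chand_n = n1 * n2 / mm
        srow = s if isinstance(s, tuple) else (s,)
        rows.append((*srow, comp, n1, n2, mm, flagged, chand_n))
    cols = strata + ["completeness", "n1", "n2", "m", "flagged", "chandra_sekar_N"]
    res = pd.DataFrame(rows, columns=cols)
    if not symmetric:
        res = res.drop(columns="chandra_sekar_N")
    return res


def correct_counts(counts: PanelCounts, completeness: pd.DataFrame) -> PanelCounts:
    """Inflate observed counts by estimated completeness.

    corrected = observed / completeness, matched on province x year (or year
    only).  Flagged strata (no reference overlap) are left uncorrected with a
    warning; completeness <= 0 is an error.
    """
    comp = completeness
    if "completeness" not in comp.columns:
        raise ValueError("completeness frame lacks a 'completeness' column")
    valid = comp.loc[~comp["flagged"], "completeness"]
    if (valid <= 0).any():
        raise ValueError("completeness must be positive in corrected strata")
    factor = np.ones(counts.shape)
    p_index = {p: i for i, p in enumerate(counts.provinces)}
    y_index = {y: i for i, y in enumerate(counts.years)}
    n_flagged = 0
    for row in comp.itertuples(index=False):
        if getattr(row, "flagged"):
            n_flagged += 1
            continue
        yi = y_index.get(int(row.year))
        if yi is None:
            continue
        if hasattr(row, "province"):
            pi = p_index.get(int(row.province))
            if pi is None:
                continue
            factor[pi, :, yi] = 1.0 / row.completeness
        else:
            factor[:, :, yi] = 1.0 / row.completeness
    if n_flagged:
        log.warning("correct_counts: %d strata flagged (no reference overlap), left uncorrected", n_flagged)
    return counts.with_events(counts.events * factor)


def remap_provinces(table: pd.DataFrame, province_map: ProvinceMap) -> pd.DataFrame:
    """Rewrite legacy province codes to the current scheme; row-conserving."""
    out = table.copy()
    present = out["province"].dropna().unique()
    unmapped = [int(c) for c in present if int(c) not in province_map.mapping]
    if unmapped:
        raise KeyError(f"province codes without a mapping: {sorted(unmapped)}")
    notna = out["province"].notna()
    out.loc[notna, "province"] = [
        province_map.mapping[int(c)] for c in out.loc[notna, "province"]
    ]
    return out


def aggregate_counts(
    table: pd.DataFrame,
    population: PopulationTable,
    age_start: int = 15,
) -> PanelCounts:
    """Bin fully-imputed records to (province, age-group, year) event counts.

    Ages are grouped in the population table's 5-year bins with the last
    group open-ended; records with age outside [0, 120] are rejected with a
    warning count, and ages below the first bin are likewise dropped (the
    analysis grid starts at the first modeled group).
    """
    for col in ("age", "province"):
        if table[col].isna().any():
            raise ValueError(f"table has missing {col}; impute first")
    P = len(population.provinces)
    A = len(population.age_groups)
    years = population.years
    y_index = {y: i for i, y in enumerate(years)}
    p_index = {p: i for i, p in enumerate(population.provinces)}
    events = np.zeros((P, A, len(years)))
    rejected = 0
    age = table["age"].astype(float).to_numpy()
    prov = table["province"].astype(int).to_numpy()
    year = table["year"].astype(int).to_numpy()
    for k in range(len(table)):
        if not (0 <= age[k] <= 120) or age[k] < age_start:
            rejected += 1
            continue
        ai = min(int((age[k] - age_start) // 5), A - 1)
        pi = p_index.get(prov[k])
        yi = y_index.get(year[k])
        if pi is None or yi is None:
            rejected += 1
            continue
        events[pi, ai, yi] += 1
    if rejected:
        log.warning("aggregate_counts: rejected %d rows outside the grid", rejected)
    return PanelCounts(
        events=events,
        person_years=population.population.astype(float),
        provinces=list(population.provinces),
        age_groups=list(population.age_groups),
        years=list(years),
    )
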