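"""Age-period-cohort analysis with the Intrinsic Estimator.

The APC design over an age-group x period Lexis grid (equal 5-year widths)
with sum-to-zero effect coding is rank-deficient by exactly one dimension
because cohort = period - age.  The Intrinsic Estimator resolves the
identification problem by choosing, among all coefficient vectors giving
the same fitted cell means, the one orthogonal to the design's null
direction B0 - equivalently the minimum-norm (Moore-Penrose) solution of
the Poisson normal equations.  Fitted means, and hence deviance, agree
with any other minimal-constraint solution; only the split of the linear
trend across age/period/cohort is pinned down by the orthogonality choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

__all__ = ["LexisTable", "APCEffects", "build_design", "null_vector", "fit_ie", "bootstrap_effects"]


@dataclass
class LexisTable:
    """Events and person-years on an age-group x period grid.

    Rows are age groups (index i = 0..A-1, youngest first), columns periods
    (j = 0..P-1, earliest first); widths equal, so the birth cohort of cell
    (i, j) has index k = (A - 1 - i) + j, giving A + P - 1 cohorts from the
    oldest (earliest-born) to the youngest.
    """

    events: np.ndarray  # (A, P)
    exposure: np.ndarray  # (A, P)
    age_labels: list[str] | None = None
    period_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if self.events.shape != self.exposure.shape:
            raise ValueError("events and exposure grids differ in shape")
        if self.events.ndim != 2 or min(self.events.shape) < 2:
            raise ValueError("need at least a 2x2 age x period grid")
        if np.any((self.events > 0) & (self.exposure <= 0)):
            raise ValueError("events observed in a cell with no exposure")

    @property
    def n_ages(self) -> int:
        return self.events.shape[0]

    @property
    def n_periods(self) -> int:
        return self.events.shape[1]

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1


def _effect_columns(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level,
    with the last level coded -1 on every column."""
    cols = np.zeros((len(levels), n_levels - 1))
    for l in range(n_levels - 1):
        cols[levels == l, l] = 1.0
    cols[levels == n_levels - 1, :] = -1.0
    return cols


def build_design(lexis: LexisTable) -> tuple[np.ndarray, np.ndarray]:
    """APC design matrix with effect coding, plus the cohort index per cell.

    Rows enumerate cells in age-major order; columns are intercept,
    (A-1) age, (P-1) period and (A+P-2) cohort contrasts.  The matrix has
    column rank (columns - 1): the age/period/cohort linear trends are
    exactly collinear, a one-dimensional null space.
    """
    A, P = lexis.n_ages, lexis.n_periods
    i_idx, j_idx = np.divmod(np.arange(A * P), P)
    k_idx = (A - 1 - i_idx) + j_idx
    X = np.column_stack(
        [
            np.ones(A * P),
            _effect_columns(i_idx, A),
            _effect_columns(j_idx, P),
            _effect_columns(k_idx, lexis.n_cohorts),
        ]
    )
    return X, k_idx


def null_vector(design: np.ndarray) -> np.ndarray:
    """Unit-norm basis of the design's null space (must be 1-dimensional);
    sign fixed so the first nonzero component is positive."""
    ns = null_space(design)
    if ns.shape[1] != 1:
        raise ValueError(f"design null space has dimension {ns.shape[1]}, expected 1")
    b0 = ns[:, 0]
    first = b0[np.nonzero(np.abs(b0) > 1e-12)[0][0]]
    if first < 0:
        b0 = -b0
    return b0 / np.linalg.norm(b0)


@dataclass
class APCEffects:
    """IE coefficients expanded to full sum-to-zero effect vectors."""

    intercept: float
    age_effects: np.ndarray  # (A,)
    period_effects: np.ndarray  # (P,)
    cohort_effects: np.ndarray  # (C,)
    age_rr: np.ndarray
    period_rr: np.ndarray
    cohort_rr: np.ndarray
    b0: np.ndarray
    coef: np.ndarray  # reduced coefficient vector (intercept + contrasts)
    deviance: float
    fitted: np.ndarray  # (A, P) fitted events

    def __post_init__(self) -> None:
        for name, eff in (
            ("age", self.age_effects),
            ("period", self.period_effects),
            ("cohort", self.cohort_effects),
        ):
            if abs(eff.sum()) > 1e-9:
                raise ValueError(f"{name} effects do not sum to zero")


def _expand(contrasts: np.ndarray) -> np.ndarray:
    return np.append(contrasts, -contrasts.sum())


def fit_ie(lexis: LexisTable, max_iter: int = 200, tol: float = 1e-12) -> APCEffects:
    """Intrinsic-Estimator Poisson fit with offset log(exposure).

    IRLS where each step solves the weighted least-squares problem by
    minimum-norm least squares; since the null space of the weighted design
    equals that of the design itself, the iterate stays orthogonal to B0
    throughout and converges to the IE solution.  Zero-exposure cells are
    dropped from the likelihood with a warning.
    """
    X, _ = build_design(lexis)
    y = lexis.events.reshape(-1)
    E = lexis.exposure.reshape(-1)
    keep = E > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-exposure cells", stacklevel=2)
    Xk, yk, Ek = X[keep], y[keep], E[keep]
    offset = np.log(Ek)
    beta = np.zeros(X.shape[1])
    dev_old = np.inf
    for _ in range(max_iter):
        eta = Xk @ beta + offset
        mu = np.exp(np.clip(eta, -500, 500))
        z = (eta - offset) + (yk - mu) / mu
        sw = np.sqrt(mu)
        beta_new, *_ = np.linalg.lstsq(sw[:, None] * Xk, sw * z, rcond=None)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * np.sum(np.where(yk > 0, yk * np.log(yk / mu), 0.0) - (yk - mu))
        if np.all(np.abs(beta_new - beta) < tol * (1 + np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
        if abs(dev_old - dev) < tol * (1 + abs(dev)):
            break
        dev_old = dev
    else:
        raise RuntimeError("IE fit did not converge")

    mu_full = np.exp(X @ beta + np.log(np.where(E > 0, E, 1.0))) * (E > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2 * np.sum(
            np.where(yk > 0, yk * np.log(yk / np.exp(Xk @ beta + offset)), 0.0)
            - (yk - np.exp(Xk @ beta + offset))
        )
    A, P, C = lexis.n_ages, lexis.n_periods, lexis.n_cohorts
    pos = 1
    age_c = beta[pos : pos + A - 1]
    pos += A - 1
    per_c = beta[pos : pos + P - 1]
    pos += P - 1
    coh_c = beta[pos : pos + C - 1]
    age_e, per_e, coh_e = _expand(age_c), _expand(per_c), _expand(coh_c)
    return APCEffects(
        intercept=float(beta[0]),
        age_effects=age_e,
        period_effects=per_e,
        cohort_effects=coh_e,
        age_rr=np.exp(age_e),
        period_rr=np.exp(per_e),
        cohort_rr=np.exp(coh_e),
        b0=null_vector(X),
        coef=beta,
        deviance=float(dev),
        fitted=mu_full.reshape(A, P),
    )


def bootstrap_effects(
    lexis: LexisTable, n_boot: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """Percentile bootstrap CIs for the relative risks.

    Events are re-sampled as Poisson around the observed cells (parametric
    bootstrap); each resample is refit with the IE.
    """
    rng = np.random.default_rng(seed)
    acc = {"age_rr": [], "period_rr": [], "cohort_rr": []}
    for _ in range(n_boot):
        ev = rng.poisson(np.maximum(lexis.events, 1e-12))
        boot = LexisTable(events=ev.astype(float), exposure=lexis.exposure)
        eff = fit_ie(boot)
        acc["age_rr"].append(eff.age_rr)
        acc["period_rr"].append(eff.period_rr)
        acc["cohort_rr"].append(eff.cohort_rr)
    out: dict[str, np.ndarray] = {}
    for key, vals in acc.items():
        arr = np.asarray(vals)
        out[f"{key}_lower"] = np.quantile(arr, alpha / 2, axis=0)
        out[f"{key}_upper"] = np.quantile(arr, 1 - alpha / 2, axis=0)
    return out
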