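"""Two-stage small-area rate estimation with draw-based uncertainty.

Stage 1 is a Poisson log-linear model of stratum event counts with an
offset of log(person-years / 100,000), fixed effects for province-year
covariates and age-group indicators, and shrunken (random-effect style)
province intercepts.  Stage 2 smooths the stage-1 log-scale residuals with
a separable space x age x time kernel that borrows strength from
neighbouring provinces, nearby age groups and nearby years.  Uncertainty
comes from Monte-Carlo draws: fixed effects are perturbed by the fitted
coefficient covariance, stratum-level observation noise is re-sampled, and
the smoothing stage is re-applied to every draw; the 2.5th and 97.5th
percentiles of the draws form the 95% uncertainty interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import statsmodels.api as sm

from .panel import PanelCounts, RateSurface
from .synthetic import CovariateTable

__all__ = [
    "SmoothingParams",
    "Stage1Fit",
    "SmoothingWeights",
    "DrawsCube",
    "fit_stage1",
    "build_weights",
    "smooth_residuals",
    "predict_log_rate",
    "sample_draws",
    "uncertainty_interval",
]

COVARIATE_COLUMNS = ["wealth", "schooling_years", "urbanization"]


@dataclass
class SmoothingParams:
    """Kernel hyperparameters.

    lambda_space in [0, 1] is the total raw weight shared across a
    province's neighbours (each neighbour gets lambda_space / degree, self
    weight 1 before normalization).  omega >= 0 is the exponential decay per
    age-group step; zeta in (0, 1] is the geometric decay per year of
    distance.  All per-axis weight rows are normalized to sum to one, so the
    induced product kernel over donor strata is a proper average.
    """

    lambda_space: float = 0.3
    omega: float = 0.7
    zeta: float = 0.8

    def validate(self) -> None:
        if not (0 <= self.lambda_space <= 1):
            raise ValueError("lambda_space must lie in [0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if not (0 < self.zeta <= 1):
            raise ValueError("zeta must lie in (0, 1]")


@dataclass
class Stage1Fit:
    """Stage-1 Poisson fit on the stratum grid."""

    beta: np.ndarray  # fixed effects
    cov_beta: np.ndarray
    feature_names: list[str]
    design: np.ndarray  # (n_strata, k), strata in (P, A, Y) C-order
    province_effects: np.ndarray  # (P,), shrunken, mean ~ 0
    eta: np.ndarray  # (P, A, Y) fitted log rate per 100,000
    residuals: np.ndarray  # (P, A, Y) log(obs rate, continuity 0.5) - eta
    obs_log_rate: np.ndarray  # (P, A, Y)
    obs_sigma: np.ndarray  # (P, A, Y) delta-method SD of obs log rate
    glm_weights: np.ndarray | None = None  # (n_strata,) IRLS weights (fitted means)
    shape: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        self.shape = self.eta.shape
        if not np.all(np.isfinite(self.residuals)):
            raise ValueError("stage-1 residuals are not finite")


def _stage1_design(counts: PanelCounts, covariates: CovariateTable) -> tuple[np.ndarray, list[str]]:
    P, A, Y = counts.shape
    cov = covariates.frame.set_index(["province", "year"]).sort_index()
    rows = []
    for p in counts.provinces:
        for y in counts.years:
            rows.append(cov.loc[(p, y), COVARIATE_COLUMNS].to_numpy(dtype=float))
    cov_py = np.asarray(rows).reshape(P, Y, len(COVARIATE_COLUMNS))
    n = P * A * Y
    k = 1 + len(COVARIATE_COLUMNS) + (A - 1)
    X = np.zeros((n, k))
    names = ["intercept", *COVARIATE_COLUMNS] + [
        f"age[{g}]" for g in counts.age_groups[1:]
    ]
    X[:, 0] = 1.0
    # strata enumerated in C-order over (P, A, Y)
    p_idx, a_idx, y_idx = np.unravel_index(np.arange(n), (P, A, Y))
    X[:, 1 : 1 + len(COVARIATE_COLUMNS)] = cov_py[p_idx, y_idx, :]
    for a in range(1, A):
        X[a_idx == a, 1 + len(COVARIATE_COLUMNS) + a - 1] = 1.0
    return X, names


def fit_stage1(
    counts: PanelCounts,
    covariates: CovariateTable,
    shrinkage_prior_var: float | None = None,
) -> Stage1Fit:
    """Fit the stage-1 Poisson model with shrunken province intercepts.

    The fixed-effect part (intercept, covariates, age indicators) is a GLM;
    province intercepts are then estimated from province-level count ratios
    and shrunk toward zero with an empirical-Bayes factor
    tau^2 / (tau^2 + v_p), where v_p is the province's sampling variance of
    the log ratio and tau^2 a method-of-moments between-province variance
    (overridable via ``shrinkage_prior_var``).  The GLM is refit once with
    the shrunken intercepts as an extra offset so the fixed effects are
    estimated net of them.  Strata with zero person-years are excluded from
    the likelihood via zero weight, not dropped.
    """
    P, A, Y = counts.shape
    X, names = _stage1_design(counts, covariates)
    y = counts.events.reshape(-1)
    py = counts.person_years.reshape(-1)
    w = (py > 0).astype(float)
    offset = np.where(py > 0, np.log(np.maximum(py, 1e-12) / 1e5), 0.0)

    def _fit(extra_offset: np.ndarray) -> sm.GLM:
        model = sm.GLM(
            y,
            X,
            family=sm.families.Poisson(),
            offset=offset + extra_offset,
            freq_weights=np.maximum(w, 1e-12),
        )
        try:
            return model.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # pragma: no cover - convergence pathology
            raise RuntimeError(f"stage-1 GLM failed to converge: {exc}") from exc

    res = _fit(np.zeros_like(y))
    mu = res.fittedvalues
    # province intercepts: log ratio of observed to fitted events
    p_idx = np.repeat(np.arange(P), A * Y)
    obs_p = np.bincount(p_idx, weights=y, minlength=P)
    fit_p = np.bincount(p_idx, weights=mu, minlength=P)
    raw_u = np.log((obs_p + 0.5) / (fit_p + 0.5))
    samp_var = 1.0 / np.maximum(obs_p, 0.5)
    if shrinkage_prior_var is None:
        tau2 = max(float(np.var(raw_u) - samp_var.mean()), 1e-6)
    else:
        tau2 = float(shrinkage_prior_var)
    shrink = tau2 / (tau2 + samp_var)
    u = shrink * raw_u
    u = u - u.mean()

    res = _fit(u[p_idx])
    eta = (X @ res.params + u[p_idx]).reshape(P, A, Y)  # log rate per 100k
    mu_fit = np.exp(eta.reshape(-1) + offset) * w
    obs_log_rate = np.log(counts.rates(continuity=0.5).clip(min=1e-12)).reshape(P, A, Y)
    residuals = np.where(w.reshape(P, A, Y) > 0, obs_log_rate - eta, 0.0)
    obs_sigma = (1.0 / np.sqrt(np.maximum(mu_fit, 0.5))).reshape(P, A, Y)
    return Stage1Fit(
        beta=res.params,
        cov_beta=np.asarray(res.cov_params()),
        feature_names=names,
        design=X,
        province_effects=u,
        eta=eta,
        residuals=residuals,
        obs_log_rate=obs_log_rate,
        obs_sigma=obs_sigma,
        glm_weights=mu_fit,
    )


# ---------------------------------------------------------------------------
# smoothing


def _row_normalize(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=1, keepdims=True)
    return W / s


@dataclass
class SmoothingWeights:
    """Separable normalized kernel over (province, age, year) strata.

    The full donor weight factorizes, w = w_space * w_age * w_time, and each
    factor is row-normalized, so the product kernel sums to one over all
    donor strata for every target stratum; smoothing reduces to three small
    matrix contractions.
    """

    w_space: np.ndarray  # (P, P)
    w_age: np.ndarray  # (A, A)
    w_time: np.ndarray  # (Y, Y)

    def weight(self, target: tuple[int, int, int], donor: tuple[int, int, int]) -> float:
        p, a, t = target
        q, b, s = donor
        return float(self.w_space[p, q] * self.w_age[a, b] * self.w_time[t, s])

    def apply(self, surface: np.ndarray) -> np.ndarray:
        out = np.einsum("pq,qay->pay", self.w_space, surface)
        out = np.einsum("ab,pby->pay", self.w_age, out)
        return np.einsum("ts,pas->pat", self.w_time, out)


def build_weights(
    adjacency: np.ndarray,
    params: SmoothingParams,
    n_ages: int,
    years: list[int] | np.ndarray,
) -> SmoothingWeights:
    """Construct the normalized space/age/time smoothing kernel.

    Raw factors: w_space = 1 on self and lambda_space/deg(p) on neighbours;
    w_age = exp(-omega |a - a'|); w_time = zeta^|y - y'|.  Each factor is
    normalized to a proper average.  A disconnected adjacency triggers a
    warning (smoothing then simply never crosses components).
    """
    params.validate()
    P = adjacency.shape[0]
    if P > 1 and not nx.is_connected(nx.from_numpy_array(adjacency)):
        warnings.warn("province adjacency graph is disconnected", stacklevel=2)
    deg = adjacency.sum(axis=1)
    w_space = np.eye(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(deg > 0, params.lambda_space / np.maximum(deg, 1), 0.0)
    w_space = w_space + adjacency * share[:, None]
    ages = np.arange(n_ages)
    dage = np.abs(ages[:, None] - ages[None, :])
    # cap the exponent so omega -> inf degenerates cleanly to self-only
    w_age = np.exp(-np.minimum(params.omega * dage, 700.0))
    yrs = np.asarray(years, dtype=float)
    dt = np.abs(yrs[:, None] - yrs[None, :])
    w_time = params.zeta**dt
    return SmoothingWeights(
        w_space=_row_normalize(w_space),
        w_age=_row_normalize(w_age),
        w_time=_row_normalize(w_time),
    )


def smooth_residuals(residuals: np.ndarray, weights: SmoothingWeights) -> np.ndarray:
    """Weighted average of residuals over donor strata (linear, rows sum 1)."""
    return weights.apply(residuals)


def predict_log_rate(stage1: Stage1Fit, weights: SmoothingWeights) -> np.ndarray:
    """Final log rate: stage-1 prediction plus smoothed residual."""
    return stage1.eta + smooth_residuals(stage1.residuals, weights)


# ---------------------------------------------------------------------------
# draws


@dataclass
class DrawsCube:
    """Monte-Carlo rate draws, shape (n_draws, P, A, Y), per 100,000."""

    draws: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.draws < 0):
            raise ValueError("rate draws must be nonnegative")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def _ensure_psd(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        warnings.warn("coefficient covariance not PSD; projecting", stacklevel=2)
    evals = np.clip(evals, 0.0, None)
    return (evecs * evals) @ evecs.T


def sample_draws(
    stage1: Stage1Fit,
    weights: SmoothingWeights,
    n_draws: int = 1000,
    seed: int = 0,
    resample_observation_noise: bool = True,
) -> DrawsCube:
    """Propagate uncertainty through both stages.

    Each draw perturbs the fixed effects by a multivariate normal with the
    fitted covariance, re-forms the residual surface against the perturbed
    prediction, re-applies the smoothing stage and exponentiates.
    Random-effect province intercepts are held fixed.

    With ``resample_observation_noise`` (the default) the draw also
    re-samples stratum-level observation noise with the delta-method
    Poisson SD, and the coefficient perturbation is derived from that same
    noise field through the GLM influence operator
    (X'WX)^{-1} X' W.  This leaves the marginal law of the coefficient
    perturbation exactly MVN(0, fitted covariance) while preserving the
    positive cross-covariance between estimation error and observation
    noise; dropping the cross-term understates the spread of the final
    estimates and the 95% intervals undercover.  Deterministic per ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    P, A, Y = stage1.shape
    p_idx = np.repeat(np.arange(P), A * Y)
    u_flat = stage1.province_effects[p_idx]
    draws = np.empty((n_draws, P, A, Y))
    coupled = resample_observation_noise and stage1.glm_weights is not None
    if coupled:
        X = stage1.design
        W = stage1.glm_weights
        influence = np.linalg.pinv(X.T @ (W[:, None] * X)) @ (X.T * W)  # (k, n)
    else:
        cov = _ensure_psd(stage1.cov_beta)
        L = np.linalg.cholesky(cov + 1e-14 * np.eye(cov.shape[0]))
    for d in range(n_draws):
        if coupled:
            nu = stage1.obs_sigma * rng.standard_normal((P, A, Y))
            beta_d = stage1.beta + influence @ nu.reshape(-1)
        else:
            nu = np.zeros((P, A, Y))
            beta_d = stage1.beta + L @ rng.standard_normal(len(stage1.beta))
        eta_d = (stage1.design @ beta_d + u_flat).reshape(P, A, Y)
        eps_d = stage1.obs_log_rate - eta_d + nu
        draws[d] = np.exp(eta_d + weights.apply(eps_d))
    return DrawsCube(draws=draws, seed=seed)


def uncertainty_interval(
    cube: DrawsCube,
    point: np.ndarray,
    provinces: list[int],
    age_groups: list[str],
    years: list[int],
) -> RateSurface:
    """Empirical 2.5th/97.5th percentile bounds around the point surface.

    Bounds are widened to bracket the point estimate where Monte-Carlo
    noise would otherwise violate lower <= point <= upper.
    """
    if cube.n_draws < 100:
        raise ValueError("need at least 100 draws for a 95% interval")
    lower = np.quantile(cube.draws, 0.025, axis=0)
    upper = np.quantile(cube.draws, 0.975, axis=0)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return RateSurface(
        rate=point,
        lower=lower,
        upper=upper,
        provinces=provinces,
        age_groups=age_groups,
        years=years,
    )
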