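"""Multinomial cause-fraction modelling and envelope allocation.

All-cause incidence/mortality envelopes are split into causes by a
multinomial logistic model of observed cause counts over stratum
predictors; predicted fractions sum to one by construction, so cause
counts conserve the envelope exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["CauseFractionModel", "fit_cause_fractions", "apply_to_envelope", "build_predictors"]


def build_predictors(
    strata: pd.DataFrame,
    age_groups: list[str] | None = None,
    provinces: list[int] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Default design: intercept + age-group indicators + centered year +
    province indicators (reference level dropped for each factor)."""
    cols: list[np.ndarray] = [np.ones(len(strata))]
    names = ["intercept"]
    if age_groups is None:
        age_groups = sorted(strata["age_group"].unique())
    for g in age_groups[1:]:
        cols.append((strata["age_group"] == g).to_numpy(float))
        names.append(f"age[{g}]")
    year = strata["year"].to_numpy(float)
    cols.append(year - year.mean())
    names.append("year")
    if provinces is None:
        provinces = sorted(strata["province"].unique())
    for p in provinces[1:]:
        cols.append((strata["province"] == p).to_numpy(float))
        names.append(f"province[{p}]")
    return np.column_stack(cols), names


@dataclass
class CauseFractionModel:
    """Fitted multinomial logit; last cause is the reference."""

    coef: np.ndarray  # (K-1, p) reference-cause coding
    causes: list[str]
    feature_names: list[str]
    cov: np.ndarray | None  # ((K-1)p, (K-1)p) Fisher-information covariance
    converged: bool

    def predict_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fractions per row, shape (n, K); rows sum to one exactly."""
        eta = X @ self.coef.T  # (n, K-1)
        eta = np.column_stack([eta, np.zeros(len(X))])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def standard_errors(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape)


def _fisher_covariance(X: np.ndarray, probs: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Inverse Fisher information of the reference-coded multinomial logit."""
    K = probs.shape[1]
    p_feat = X.shape[1]
    dim = (K - 1) * p_feat
    info = np.zeros((dim, dim))
    for j in range(K - 1):
        for l in range(K - 1):
            w = n * (probs[:, j] * ((j == l) - probs[:, l]))
            block = X.T @ (w[:, None] * X)
            info[j * p_feat : (j + 1) * p_feat, l * p_feat : (l + 1) * p_feat] = block
    return np.linalg.pinv(info)


def fit_cause_fractions(
    cause_counts: pd.DataFrame,
    causes: list[str],
    X: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> CauseFractionModel:
    """Maximum-likelihood multinomial logit of cause counts per stratum.

    ``cause_counts`` is tidy with one row per stratum x cause and columns
    including ``cause`` and ``count`` plus the stratum identifiers
    (province, age_group, year) used by the default predictor builder.
    A custom design ``X`` must have one row per stratum in sorted
    (province, age_group, year) order.  Separation / non-convergence falls
    back to a weak ridge with a warning.
    """
    if len(causes) < 2:
        raise ValueError("need at least 2 causes")
    missing = set(causes) - set(cause_counts["cause"].unique())
    if missing:
        raise ValueError(f"causes never observed: {sorted(missing)}")
    wide = (
        cause_counts.pivot_table(
            index=["province", "age_group", "year"],
            columns="cause",
            values="count",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=causes, fill_value=0.0)
        .reset_index()
    )
    if X is None:
        X, feature_names = build_predictors(wide)
    counts = wide[causes].to_numpy(float)

    # expand to one weighted row per (stratum, cause) for the solver
    n_strata, K = counts.shape
    Xrep = np.repeat(X, K, axis=0)
    yrep = np.tile(np.arange(K), n_strata)
    wrep = counts.reshape(-1)
    keep = wrep > 0
    clf = LogisticRegression(
        C=np.inf, solver="newton-cg", max_iter=5000, tol=1e-12, fit_intercept=False
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            clf.fit(Xrep[keep], yrep[keep], sample_weight=wrep[keep])
        except (ConvergenceWarning, np.linalg.LinAlgError):
            warnings.simplefilter("default", category=ConvergenceWarning)
            warnings.warn(
                "multinomial fit did not converge (separation?); "
                "refitting with a weak ridge",
                stacklevel=2,
            )
            converged = False
            clf = LogisticRegression(
                C=1e4, solver="newton-cg", max_iter=5000, fit_intercept=False
            )
            clf.fit(Xrep[keep], yrep[keep], sample_weight=wrep[keep])
    if K == 2:
        # binary sklearn fit parameterizes log odds of class 1 (the reference
        # here is the last cause, class K-1), so negate for cause-0 coding
        coef = -clf.coef_
    else:
        full = clf.coef_[np.argsort(clf.classes_)]
        coef = full[:-1] - full[-1]  # reference-cause coding, last cause baseline
    model = CauseFractionModel(
        coef=coef,
        causes=list(causes),
        feature_names=feature_names or [f"x{i}" for i in range(X.shape[1])],
        cov=None,
        converged=converged,
    )
    probs = model.predict_fractions(X)
    model.cov = _fisher_covariance(X, probs, counts.sum(axis=1))
    return model


def apply_to_envelope(
    model: CauseFractionModel,
    envelope: pd.DataFrame,
    X: np.ndarray | None = None,
) -> pd.DataFrame:
    """Allocate all-cause stratum counts to causes.

    ``envelope`` is tidy with province/age_group/year and an ``events``
    column.  Returns one row per stratum x cause; cause counts sum to the
    envelope exactly in every stratum.
    """
    if (envelope["events"] < 0).any():
        raise ValueError("envelope counts must be nonnegative")
    if X is None:
        X, _ = build_predictors(envelope)
    fr = model.predict_fractions(X)
    out = []
    for j, cause in enumerate(model.causes):
        part = envelope[["province", "age_group", "year"]].copy()
        part["cause"] = cause
        part["count"] = fr[:, j] * envelope["events"].to_numpy(float)
        out.append(part)
    return pd.concat(out, ignore_index=True)
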