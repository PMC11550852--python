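"""Convergence regression: country fixed effects, cluster-robust inference.

The model is

    ratio_it = alpha + beta * base_it + x_it' delta + gamma_i + eps_it,

with gamma_i a country intercept (absorbed by within-country demeaning) and
eps_it allowed arbitrary correlation within country.  beta < 0 is
convergence: countries starting high decline proportionally faster per unit
of the denominator (time or education).

Inference uses the CR1 cluster-robust sandwich,

    V = c * (X'X)^{-1} [ sum_g X_g' e_g e_g' X_g ] (X'X)^{-1},
    c = G/(G-1) * (N-1)/(N-K),

with G clusters (countries), N observations, and K the number of model
parameters *including* the absorbed country intercepts, so that the within
transformation and explicit least-squares-dummy-variables (LSDV) estimation
give identical standard errors.  Confidence intervals and p-values use the
t distribution with G - 1 degrees of freedom.

:func:`lsdv_oracle` re-computes the same estimand by brute force (explicit
country dummies, per-cluster meat-matrix loop); it exists for equivalence
testing and deliberately shares no linear-algebra path with
:func:`fit_convergence`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import IdentificationError, InferenceError
from .sample_builder import ConvergenceSample

#: relative pivot threshold for declaring a design singular
_RANK_TOL = 1e-10


@dataclass
class FitResult:
    """Convergence fit: point estimate, cluster-robust inference, bookkeeping."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    n_obs: int
    n_countries: int
    n_trimmed: int = 0
    n_zero_delta: int = 0
    converged_flag: str = "null"  # "convergence" | "divergence" | "null"
    df: int = 0
    fixed_effects: bool = True
    standardized: bool = False
    covariates: dict[str, float] = dataclasses.field(default_factory=dict)
    fert_indicator: str = ""
    edu_indicator: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_row(self) -> dict:
        """Flat scalar mapping for a results-table row."""
        row = self.to_dict()
        covs = row.pop("covariates")
        for name, val in covs.items():
            row[f"coef_{name}"] = val
        return row


def _flag(beta: float, ci_low: float, ci_high: float) -> str:
    if beta < 0 and ci_high < 0:
        return "convergence"
    if beta > 0 and ci_low > 0:
        return "divergence"
    return "null"


def cluster_vcov(
    X: np.ndarray,
    resid: np.ndarray,
    groups: np.ndarray,
    k_params: int | None = None,
) -> np.ndarray:
    """CR1 cluster-robust sandwich variance of OLS coefficients.

    ``k_params`` is the parameter count used in the small-sample factor
    (N-1)/(N-K); pass the *full* model dimension when ``X`` is an
    already-demeaned design whose absorbed intercepts should still count.
    Raises :class:`InferenceError` with fewer than 2 clusters and
    :class:`IdentificationError` for a singular X'X.
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    groups = np.asarray(groups)
    n, k = X.shape
    if k_params is None:
        k_params = k
    labels, inverse = np.unique(groups, return_inverse=True)
    G = len(labels)
    if G < 2:
        raise InferenceError("cluster-robust variance requires >= 2 clusters")
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1 / _RANK_TOL:
        raise IdentificationError("singular design in cluster_vcov")
    bread = np.linalg.inv(xtx)
    # meat: sum_g (X_g' e_g)(X_g' e_g)'; accumulate scores per cluster
    scores = X * resid[:, None]
    summed = np.zeros((G, k))
    np.add.at(summed, inverse, scores)
    meat = summed.T @ summed
    c = (G / (G - 1)) * ((n - 1) / (n - k_params))
    return c * bread @ meat @ bread


def _design(
    sample: ConvergenceSample, covariate_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = sample.data
    y = data["ratio"].to_numpy(dtype=float)
    X = data[["base_fertility", *covariate_names]].to_numpy(dtype=float)
    groups = data["country"].to_numpy()
    return y, X, groups


def fit_convergence(
    sample: ConvergenceSample,
    fixed_effects: bool = True,
    covariate_names: tuple[str, ...] | None = None,
    conf_level: float = 0.95,
) -> FitResult:
    """Estimate the convergence coefficient beta.

    With ``fixed_effects`` the outcome and regressors are demeaned within
    country (the within transformation) and the common slope is estimated on
    the demeaned data; the reported ``alpha`` is then the grand intercept
    ȳ - β·x̄.  Without fixed effects a plain intercept model is fit.  In both
    cases the standard error is the CR1 cluster sandwich with countries as
    clusters, and the CI / p-value use t(G-1).

    Raises :class:`IdentificationError` when the slope is not identified
    (e.g. no within-country variation in base fertility under FE) and
    :class:`InferenceError` with fewer than 2 clusters.
    """
    if covariate_names is None:
        covariate_names = sample.covariate_names
    covariate_names = tuple(covariate_names)
    y, X, groups = _design(sample, covariate_names)
    n = len(y)
    labels, inverse = np.unique(groups, return_inverse=True)
    G = len(labels)
    n_slopes = X.shape[1]

    if fixed_effects:
        k_params = n_slopes + G  # slopes + absorbed country intercepts
        if n < k_params:
            raise IdentificationError(
                f"{n} observations cannot identify {n_slopes} slope(s) "
                f"plus {G} country intercepts"
            )
        counts = np.bincount(inverse).astype(float)
        y_c = y - (np.bincount(inverse, weights=y) / counts)[inverse]
        X_c = np.empty_like(X)
        for j in range(n_slopes):
            X_c[:, j] = X[:, j] - (
                np.bincount(inverse, weights=X[:, j]) / counts
            )[inverse]
        design = X_c
        y_fit = y_c
    else:
        k_params = n_slopes + 1
        if n < k_params:
            raise IdentificationError("more parameters than observations")
        design = np.column_stack([np.ones(n), X])
        y_fit = y

    xtx = design.T @ design
    scale = np.sqrt(np.diag(xtx))
    if np.any(scale == 0) or np.linalg.cond(xtx) > 1 / _RANK_TOL:
        raise IdentificationError(
            "singular design: no usable variation in a regressor"
            + (" after within-country demeaning" if fixed_effects else "")
        )
    coefs = np.linalg.solve(xtx, design.T @ y_fit)
    resid = y_fit - design @ coefs

    if G < 2:
        raise InferenceError(
            "cluster-robust inference requires >= 2 countries (clusters)"
        )
    vcov = cluster_vcov(design, resid, groups, k_params=k_params)

    if fixed_effects:
        beta_idx = 0
        alpha = float(y.mean() - X.mean(axis=0) @ coefs)
        slope_names = ["base_fertility", *covariate_names]
        slopes = dict(zip(slope_names, coefs))
    else:
        beta_idx = 1
        alpha = float(coefs[0])
        slope_names = ["base_fertility", *covariate_names]
        slopes = dict(zip(slope_names, coefs[1:]))

    beta = float(slopes["base_fertility"])
    se = float(np.sqrt(vcov[beta_idx, beta_idx]))
    df = G - 1
    tcrit = stats.t.ppf(0.5 + conf_level / 2, df)
    ci_low, ci_high = beta - tcrit * se, beta + tcrit * se
    tstat = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2 * stats.t.sf(abs(tstat), df)

    return FitResult(
        beta=beta,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        alpha=alpha,
        n_obs=n,
        n_countries=G,
        n_trimmed=sample.n_trimmed,
        n_zero_delta=sample.n_zero_delta,
        converged_flag=_flag(beta, ci_low, ci_high),
        df=df,
        fixed_effects=fixed_effects,
        standardized=sample.standardized,
        covariates={k: float(v) for k, v in slopes.items() if k != "base_fertility"},
        fert_indicator=sample.fert_indicator,
        edu_indicator=sample.edu_indicator,
    )


def lsdv_oracle(
    sample: ConvergenceSample,
    covariate_names: tuple[str, ...] | None = None,
    conf_level: float = 0.95,
    compute_se: bool = True,
) -> FitResult:
    """Brute-force fixed-effects fit via explicit country dummies.

    Solves the least-squares-dummy-variables regression directly (one
    indicator column per country, no common intercept) and, when
    ``compute_se``, forms the CR1 sandwich with an explicit per-cluster
    Python loop.  Numerically equivalent to ``fit_convergence`` with fixed
    effects by the Frisch–Waugh–Lovell theorem; kept as an independent
    implementation for testing.  With a single country (``compute_se=False``)
    the slope reduces to that country's own OLS slope.
    """
    if covariate_names is None:
        covariate_names = sample.covariate_names
    covariate_names = tuple(covariate_names)
    y, X, groups = _design(sample, covariate_names)
    n = len(y)
    labels = sorted(pd.unique(groups))
    G = len(labels)
    n_slopes = X.shape[1]

    dummies = np.zeros((n, G))
    for j, lab in enumerate(labels):
        dummies[groups == lab, j] = 1.0
    full = np.hstack([X, dummies])
    k_params = n_slopes + G
    if n < k_params or np.linalg.matrix_rank(full) < k_params:
        raise IdentificationError("singular LSDV design")

    coefs, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ coefs
    beta = float(coefs[0])
    gamma = coefs[n_slopes:]
    alpha = float(np.mean(gamma[pd.Categorical(groups, categories=labels).codes]))

    se = np.nan
    ci_low = ci_high = p = np.nan
    df = G - 1
    if compute_se:
        if G < 2:
            raise InferenceError("clustered SE needs >= 2 countries")
        bread = np.linalg.inv(full.T @ full)
        meat = np.zeros((k_params, k_params))
        for lab in labels:
            idx = groups == lab
            score = full[idx].T @ resid[idx]
            meat += np.outer(score, score)
        c = (G / (G - 1)) * ((n - 1) / (n - k_params))
        vcov = c * bread @ meat @ bread
        se = float(np.sqrt(vcov[0, 0]))
        tcrit = stats.t.ppf(0.5 + conf_level / 2, df)
        ci_low, ci_high = beta - tcrit * se, beta + tcrit * se
        p = float(2 * stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0

    flag = _flag(beta, ci_low, ci_high) if compute_se else "null"
    return FitResult(
        beta=beta,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        alpha=alpha,
        n_obs=n,
        n_countries=G,
        n_trimmed=sample.n_trimmed,
        n_zero_delta=sample.n_zero_delta,
        converged_flag=flag,
        df=df,
        fixed_effects=True,
        standardized=sample.standardized,
        covariates=dict(zip(covariate_names, map(float, coefs[1:n_slopes]))),
        fert_indicator=sample.fert_indicator,
        edu_indicator=sample.edu_indicator,
    )
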