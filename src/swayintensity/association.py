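"""Associations between ratings, exercise difficulty, and sway kinematics.

Three analyses live here:

* Difficulty regression — the rating regressed on one coded difficulty
  dimension (surface, stance, vision or head movement) with crossed random
  intercepts for balance participant and PT rater. The slope says how many
  rating points one code step is worth.
* Feature-rating correlation — a mixed model ``rating ~ feature + (1 |
  participant)``; the marginal correlation is derived from the variance the
  fixed feature effect explains::

      R^2 = s2_f / (s2_f + s2_alpha + s2_eps),   s2_f = var(beta * x)

  with ``s2_alpha`` the participant random-intercept variance and ``s2_eps``
  the error variance; ``r`` carries the sign of the slope. ``var`` is the
  population variance of the fitted fixed-effect contribution over the
  analyzed rows.
* Spearman rank correlation between paired rating modes, with average ranks
  for ties, a Fisher-z confidence interval and a t-approximation p-value.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (DegenerateDataError, InsufficientDataError,
                     UndefinedStatisticError)
from .varcomp import fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "CorrelationResult",
    "difficulty_regression",
    "difficulty_regression_joint",
    "feature_rating_correlation",
    "marginal_r_squared",
    "spearman_agreement",
    "DIFFICULTY_DIMENSIONS",
]

DIFFICULTY_DIMENSIONS = ("surface", "stance", "vision", "head_movement")


@dataclass
class RegressionResult:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    n_obs: int


@dataclass
class CorrelationResult:
    feature: str
    transform: str              # "none" | "log"
    r: float
    r_squared: float
    sigma_f_sq: float
    sigma_alpha_sq: float
    sigma_eps_sq: float
    beta: float
    p_value: float
    n_obs: int
    n_excluded: int = 0


def _select_level(ratings: pd.DataFrame, level: str) -> pd.DataFrame:
    pt = ratings[ratings["rater_type"] == "pt"]
    if level == "trial":
        return pt[pt["trial"].notna()]
    if level == "exercise":
        return pt[pt["trial"].isna()]
    raise ValueError(f"level must be 'trial' or 'exercise', got {level!r}")


def difficulty_regression(
    ratings: pd.DataFrame,
    exercises: pd.DataFrame,
    dimension: str,
    level: str = "trial",
    value_col: str = "rating",
) -> RegressionResult:
    """Mixed-model slope of PT ratings on one coded difficulty dimension.

    Fixed part: intercept + the dimension code; random intercepts for
    balance participant and PT rater (crossed). Wald 95% interval and
    two-sided normal p-value for the slope.
    """
    if dimension not in DIFFICULTY_DIMENSIONS:
        raise ValueError(f"unknown difficulty dimension {dimension!r}")
    sub = _select_level(ratings, level).merge(
        exercises[["exercise_id", dimension]], on="exercise_id", how="inner")
    if len(sub) == 0:
        raise InsufficientDataError("no PT ratings joined to exercise codes")
    x = sub[dimension].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDataError(
            f"dimension {dimension!r} has a single level; no contrast to estimate"
        )
    X = np.column_stack([np.ones(len(sub)), x])
    terms = {"participant": sub["participant_id"].to_numpy(),
             "rater": sub["rater_id"].to_numpy()}
    # a single participant or rater carries no grouping information
    terms = {k: v for k, v in terms.items() if len(np.unique(v)) >= 2}
    fit = fit_lmm(sub[value_col].to_numpy(dtype=float), X, terms)
    est = float(fit.beta[1])
    se = float(math.sqrt(fit.cov_beta[1, 1]))
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else math.nan
    return RegressionResult(term=dimension, estimate=est,
                            ci_low=est - z * se, ci_high=est + z * se,
                            p_value=float(p), se=se, n_obs=len(sub))


def difficulty_regression_joint(
    ratings: pd.DataFrame,
    exercises: pd.DataFrame,
    level: str = "trial",
    value_col: str = "rating",
) -> list:
    """All four difficulty dimensions as simultaneous fixed slopes (same
    random structure as the one-at-a-time model); returns one
    :class:`RegressionResult` per dimension."""
    sub = _select_level(ratings, level).merge(
        exercises[["exercise_id", *DIFFICULTY_DIMENSIONS]],
        on="exercise_id", how="inner")
    if len(sub) == 0:
        raise InsufficientDataError("no PT ratings joined to exercise codes")
    codes = sub[list(DIFFICULTY_DIMENSIONS)].to_numpy(dtype=float)
    for j, dim in enumerate(DIFFICULTY_DIMENSIONS):
        if len(np.unique(codes[:, j])) < 2:
            raise DegenerateDataError(
                f"dimension {dim!r} has a single level; no contrast to estimate"
            )
    X = np.column_stack([np.ones(len(sub)), codes])
    terms = {"participant": sub["participant_id"].to_numpy(),
             "rater": sub["rater_id"].to_numpy()}
    terms = {k: v for k, v in terms.items() if len(np.unique(v)) >= 2}
    fit = fit_lmm(sub[value_col].to_numpy(dtype=float), X, terms)
    z = stats.norm.ppf(0.975)
    out = []
    for j, dim in enumerate(DIFFICULTY_DIMENSIONS, start=1):
        est = float(fit.beta[j])
        se = float(math.sqrt(fit.cov_beta[j, j]))
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else math.nan
        out.append(RegressionResult(term=dim, estimate=est,
                                    ci_low=est - z * se, ci_high=est + z * se,
                                    p_value=float(p), se=se, n_obs=len(sub)))
    return out


def feature_rating_correlation(
    ratings: pd.DataFrame,
    features: pd.DataFrame,
    feature_name: str,
    transform: str = "none",
    value_col: str = "rating",
) -> CorrelationResult:
    """Marginal correlation between one kinematic feature and per-trial PT
    ratings from ``rating ~ feature + (1 | participant)``.

    With ``transform="log"`` the natural-log column is used; rows whose log
    is undefined (zero feature) are excluded and counted.
    """
    if transform not in ("none", "log"):
        raise ValueError("transform must be 'none' or 'log'")
    col = feature_name if transform == "none" else f"log_{feature_name}"
    if col not in features.columns:
        raise KeyError(f"feature column {col!r} not present")
    pt = _select_level(ratings, "trial")
    merged = pt.merge(features, on=["participant_id", "exercise_id", "trial"],
                      how="inner")
    n_before = len(merged)
    merged = merged[np.isfinite(merged[col].to_numpy(dtype=float))]
    n_excl = n_before - len(merged)
    if n_excl:
        logger.info("excluded %d rows with undefined %s", n_excl, col)
    if len(merged) < 3:
        raise InsufficientDataError("fewer than 3 usable rating-feature pairs")
    x = merged[col].to_numpy(dtype=float)
    if np.var(x) == 0.0:
        raise UndefinedStatisticError(f"feature {col!r} has zero variance")

    md = sm.MixedLM(merged[value_col].to_numpy(dtype=float),
                    sm.add_constant(x),
                    groups=merged["participant_id"].to_numpy())
    with warnings.catch_warnings():
        # a participant variance on the zero boundary triggers retries; the
        # returned estimates are still the constrained optimum
        warnings.simplefilter("ignore")
        fit = md.fit(reml=True)
    beta = float(fit.fe_params[1])
    sigma_alpha = float(np.asarray(fit.cov_re)[0, 0])
    sigma_eps = float(fit.scale)
    sigma_f = float(np.var(beta * x))       # population variance, ddof=0
    r2 = marginal_r_squared(sigma_f, sigma_alpha, sigma_eps)
    r = math.copysign(math.sqrt(r2), beta)
    p = float(fit.pvalues[1])
    return CorrelationResult(feature=feature_name, transform=transform,
                             r=r, r_squared=r2, sigma_f_sq=sigma_f,
                             sigma_alpha_sq=sigma_alpha, sigma_eps_sq=sigma_eps,
                             beta=beta, p_value=p, n_obs=len(merged),
                             n_excluded=n_excl)


def marginal_r_squared(sigma_f_sq: float, sigma_alpha_sq: float,
                       sigma_eps_sq: float) -> float:
    """Variance explained by the fixed feature effect, as a fraction of the
    marginal (fixed + participant + error) variance."""
    denom = sigma_f_sq + sigma_alpha_sq + sigma_eps_sq
    if denom <= 0:
        raise UndefinedStatisticError("total marginal variance is zero")
    return float(sigma_f_sq / denom)


def spearman_agreement(x, y, alpha: float = 0.05):
    """Spearman rho with average ranks for ties, Fisher-z CI, and a two-sided
    t-approximation p-value. Returns ``(rho, ci_low, ci_high, p_value)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("a constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 or n <= 3:
        return rho, rho, rho, float(p)
    z = np.arctanh(rho)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / math.sqrt(n - 3)
    return rho, float(np.tanh(z - half)), float(np.tanh(z + half)), float(p)
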