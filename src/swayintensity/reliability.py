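"""Inter-rater reliability of PT intensity ratings via variance decomposition.

The per-trial model treats the rating as continuous with fixed effects for
the intercept and trial number and a random effect for every main effect and
interaction among trial, exercise, balance participant and PT rater (terms
aliased with the residual — e.g. the four-way interaction when each rater
scores each trial once — are dropped automatically). The ICC for absolute
agreement of single ratings, the ICC(2,1) analogue for this crossed design,
is the fraction of total variance *shared* across raters::

    ICC = 1 - (rater-involving variance + residual) / total variance

i.e. variance components whose term involves the rater, plus the residual,
count against agreement. The complementary literal ratio
(rater-involving / total) is reported alongside for transparency. The
per-exercise model is identical minus every trial-involving term.

Interpretation bands: < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good,
>= 0.9 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import (IdentifiabilityError, InsufficientDataError,
                     UndefinedStatisticError)
from .varcomp import LMMFit, balanced_anova_components, fit_lmm

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "default_random_terms",
    "fit_variance_components",
    "icc_from_components",
    "interpret_icc",
    "icc_analysis",
]

_FACTOR_COLUMNS = {
    "participant": "participant_id",
    "rater": "rater_id",
    "exercise": "exercise_id",
    "trial": "trial",
}


@dataclass
class VarianceComponents:
    """Named nonnegative variance estimates from a crossed random-effects fit."""

    components: dict            # term label -> variance (>= 0)
    residual: float
    fixed_effects: dict         # term -> estimate
    converged: bool = True
    dropped_terms: tuple = ()
    method: str = "reml"
    message: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.components.values()) + self.residual)


@dataclass
class ICCResult:
    icc: float
    literal_rater_ratio: float     # rater-involving / total, as literally read
    rater_involving_variance: float
    total_variance: float
    category: str


def default_random_terms(factors=("participant", "rater", "exercise", "trial")):
    """All main effects and interactions among the given factors."""
    out = []
    for r in range(1, len(factors) + 1):
        for combo in combinations(factors, r):
            out.append("×".join(combo))
    return tuple(out)


def _term_codes(ratings: pd.DataFrame, label: str) -> np.ndarray:
    cols = [_FACTOR_COLUMNS[f] for f in label.split("×")]
    if len(cols) == 1:
        return ratings[cols[0]].to_numpy()
    return np.asarray(list(zip(*(ratings[c].astype(str) for c in cols))), dtype=object)


def fit_variance_components(
    ratings: pd.DataFrame,
    fixed_terms: tuple = ("trial",),
    random_terms: tuple | None = None,
    value_col: str = "rating",
    method: str = "reml",
    anova_clip: bool = True,
    **fit_kwargs,
) -> VarianceComponents:
    """Decompose rating variance over crossed random terms.

    ``method="reml"`` handles arbitrary (unbalanced) designs; ``"anova"``
    requires a balanced fully crossed design over the main factors and an
    intercept-only fixed part, and uses the closed-form expected-mean-squares
    estimator.
    """
    if ratings is None or len(ratings) == 0:
        raise InsufficientDataError("no ratings to decompose")
    if random_terms is None:
        random_terms = default_random_terms()
    y = ratings[value_col].to_numpy(dtype=float)

    if method == "anova":
        if fixed_terms not in ((), None):
            raise IdentifiabilityError(
                "the balanced ANOVA path supports an intercept-only fixed part"
            )
        mains = [t for t in random_terms if "×" not in t]
        cols = [_FACTOR_COLUMNS[m] for m in mains]
        tab = ratings.set_index(cols)[value_col]
        shape = [ratings[c].nunique() for c in cols]
        if len(tab) != int(np.prod(shape)) or tab.index.duplicated().any():
            raise IdentifiabilityError(
                "design is not balanced fully crossed; use method='reml'"
            )
        arr = tab.sort_index().to_numpy(dtype=float).reshape(shape)
        comps = balanced_anova_components(arr, mains, clip=anova_clip)
        residual = comps.pop("residual")
        kept = {t: comps[t] for t in random_terms if t in comps}
        return VarianceComponents(
            components=kept, residual=float(residual),
            fixed_effects={"intercept": float(np.mean(y))},
            converged=True, method="anova",
            dropped_terms=tuple(t for t in random_terms if t not in comps),
        )

    X_cols = [np.ones(len(ratings))]
    fe_names = ["intercept"]
    for t in fixed_terms or ():
        X_cols.append(ratings[_FACTOR_COLUMNS[t]].to_numpy(dtype=float))
        fe_names.append(t)
    X = np.column_stack(X_cols)
    terms = {label: _term_codes(ratings, label) for label in random_terms}
    fit: LMMFit = fit_lmm(y, X, terms, **fit_kwargs)
    return VarianceComponents(
        components=fit.components,
        residual=fit.residual,
        fixed_effects=dict(zip(fe_names, fit.beta)),
        converged=fit.converged,
        dropped_terms=fit.dropped_terms,
        method="reml",
        message=fit.message,
    )


def interpret_icc(icc: float) -> str:
    """Reliability band for an ICC value (left-closed boundaries)."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC must lie in [0, 1], got {icc}")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_from_components(
    components: VarianceComponents, rater_label: str = "rater"
) -> ICCResult:
    """ICC for absolute agreement from a variance decomposition.

    Rater-involving variance = every component whose term includes
    ``rater_label``, plus the residual. ICC = shared / total = 1 minus the
    rater-involving fraction.
    """
    total = components.total
    if total <= 0.0:
        raise UndefinedStatisticError("total variance is zero; ICC undefined")
    rater_inv = components.residual + sum(
        v for label, v in components.components.items()
        if rater_label in label.split("×")
    )
    literal = rater_inv / total
    icc = 1.0 - literal
    return ICCResult(icc=float(icc), literal_rater_ratio=float(literal),
                     rater_involving_variance=float(rater_inv),
                     total_variance=float(total),
                     category=interpret_icc(icc))


def icc_analysis(
    ratings: pd.DataFrame,
    level: str = "trial",
    value_col: str = "rating",
    method: str = "reml",
    **fit_kwargs,
):
    """Per-trial or per-exercise inter-rater reliability of PT ratings.

    Filters to PT ratings at the requested level, fits the corresponding
    variance-components model (trial-involving random terms and the trial
    fixed effect are dropped at the exercise level) and returns
    ``(ICCResult, VarianceComponents)``.
    """
    pt = ratings[ratings["rater_type"] == "pt"]
    if level == "trial":
        sub = pt[pt["trial"].notna()].copy()
        fixed = ("trial",)
        rand = default_random_terms(("participant", "rater", "exercise", "trial"))
    elif level == "exercise":
        sub = pt[pt["trial"].isna()].copy()
        fixed = ()
        rand = default_random_terms(("participant", "rater", "exercise"))
    else:
        raise ValueError(f"level must be 'trial' or 'exercise', got {level!r}")
    if len(sub) == 0:
        raise InsufficientDataError(f"no PT ratings at level {level!r}")
    if method == "anova":
        fixed = ()
    vc = fit_variance_components(sub, fixed_terms=fixed, random_terms=rand,
                                 value_col=value_col, method=method, **fit_kwargs)
    return icc_from_components(vc), vc
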