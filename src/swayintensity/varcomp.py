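"""Linear mixed models with crossed variance components.

The model is ``y = X beta + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k I)``
for each random term (a factor or factor interaction, fully crossed or not)
and ``e ~ N(0, s2_e I)``. Two estimators are provided:

* :func:`fit_lmm` — profiled REML. The residual variance and fixed effects
  are profiled out analytically; the variance ratios ``gamma_k = s2_k/s2_e``
  are optimized with L-BFGS-B under nonnegativity bounds. Likelihood
  evaluations use the Woodbury identity on the (sparse) indicator matrices,
  so cost scales with the number of random-effect levels rather than with n.
* :func:`balanced_anova_components` — closed-form expected-mean-squares
  (method-of-moments) estimates for balanced, fully crossed designs. Exact
  and fast; used both as a production path for balanced data and as an
  independent check on the REML path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .errors import IdentifiabilityError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["LMMFit", "fit_lmm", "balanced_anova_components"]

# dense linear algebra below this many random-effect levels
_DENSE_LIMIT = 600


@dataclass
class LMMFit:
    """Result of a crossed random-effects REML fit."""

    beta: np.ndarray                 # fixed-effect estimates
    cov_beta: np.ndarray             # Wald covariance of beta
    components: dict                 # term label -> variance estimate (>= 0)
    residual: float                  # residual variance
    converged: bool
    neg2_reml: float
    n_obs: int
    dropped_terms: tuple = ()
    message: str = ""

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()) + self.residual)


def _encode_terms(terms: Mapping[str, Sequence], n: int):
    """Factorize term codes; drop terms aliased with the residual or with an
    earlier term (identical partition of the observations)."""
    encoded = {}
    dropped = []
    seen_partitions = {}
    for label, raw in terms.items():
        raw = np.asarray(raw)
        if raw.shape[0] != n:
            raise IdentifiabilityError(f"term {label!r} has wrong length")
        codes, uniques = pd.factorize(raw if raw.ndim == 1
                                      else pd.Series(list(map(tuple, raw))))
        q = len(uniques)
        if q == 1:
            raise IdentifiabilityError(
                f"random term {label!r} has a single level and is not identifiable"
            )
        if q == n:
            dropped.append(label)
            logger.info("dropping term %r: one observation per level "
                        "(aliased with residual)", label)
            continue
        key = codes.tobytes()
        if key in seen_partitions:
            dropped.append(label)
            logger.info("dropping term %r: identical grouping to %r",
                        label, seen_partitions[key])
            continue
        seen_partitions[key] = label
        encoded[label] = (codes.astype(np.int64), q)
    return encoded, tuple(dropped)


def _indicator(codes: np.ndarray, q: int) -> sp.csc_matrix:
    n = len(codes)
    return sp.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )


def fit_lmm(
    y: Sequence[float],
    X: np.ndarray,
    terms: Mapping[str, Sequence],
    maxiter: int = 200,
    gtol: float = 1e-7,
) -> LMMFit:
    """Fit the crossed variance-components model by profiled REML.

    Parameters
    ----------
    y : response vector (n,)
    X : fixed-effects design matrix (n, p); must be full column rank
    terms : mapping from term label to a length-n vector (or n x m array of
        tuples) of group codes; one variance component per term
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if n == 0:
        raise InsufficientDataError("empty response vector")
    if X.shape[0] != n:
        raise IdentifiabilityError("X and y have different lengths")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise IdentifiabilityError("fixed-effects design matrix is rank deficient")
    if n <= p:
        raise InsufficientDataError("need more observations than fixed effects")

    encoded, dropped = _encode_terms(terms, n)
    labels = list(encoded)
    K = len(labels)

    # scale y for conditioning; variances are rescaled on the way out
    scale = float(np.std(y))
    if scale == 0.0:
        scale = 1.0
    ys = y / scale

    XtX = X.T @ X
    Xty = X.T @ ys
    yty = float(ys @ ys)

    if K == 0:
        beta = np.linalg.solve(XtX, Xty)
        rss = yty - Xty @ beta
        sigma_e2 = max(rss / (n - p), 0.0)
        return LMMFit(beta=beta * scale,
                      cov_beta=sigma_e2 * np.linalg.inv(XtX) * scale**2,
                      components={}, residual=sigma_e2 * scale**2,
                      converged=True, neg2_reml=np.nan, n_obs=n,
                      dropped_terms=dropped, message="no random terms; OLS")

    Zs = [_indicator(*encoded[l]) for l in labels]
    Z = sp.hstack(Zs, format="csc")
    q_sizes = np.array([encoded[l][1] for l in labels])
    block = np.repeat(np.arange(K), q_sizes)
    ZtZ = (Z.T @ Z).tocsc()
    ZtX = Z.T @ X            # dense (q, p)
    Zty = Z.T @ ys
    q_total = int(q_sizes.sum())
    use_dense = q_total <= _DENSE_LIMIT
    ZtZ_d = ZtZ.toarray() if use_dense else None

    def profile(gamma: np.ndarray):
        w = gamma[block]                       # per-column variance ratio
        sw = np.sqrt(np.maximum(w, 0.0))
        rhs = np.column_stack([ZtX, Zty]) * sw[:, None]   # (q, p+1)
        if use_dense:
            B = ZtZ_d * np.outer(sw, sw)
            B[np.diag_indices_from(B)] += 1.0
            sign, logdetB = np.linalg.slogdet(B)
            sol = np.linalg.solve(B, rhs)
        else:
            D = sp.diags(sw)
            B = (sp.eye(q_total) + D @ ZtZ @ D).tocsc()
            lu = spla.splu(B)
            logdetB = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            sol = lu.solve(rhs)
        XtHiX = XtX - rhs[:, :p].T @ sol[:, :p]
        XtHiy = Xty - rhs[:, :p].T @ sol[:, p]
        yHiy = yty - rhs[:, p] @ sol[:, p]
        beta = np.linalg.solve(XtHiX, XtHiy)
        yPy = max(yHiy - XtHiy @ beta, 1e-12)
        sign2, logdetXtHiX = np.linalg.slogdet(XtHiX)
        neg2 = (n - p) * np.log(yPy / (n - p)) + logdetB + logdetXtHiX
        return neg2, beta, XtHiX, yPy

    def objective(gamma: np.ndarray) -> float:
        return profile(gamma)[0]

    x0 = np.full(K, 1.0 / (K + 1))
    res = minimize(objective, x0, method="L-BFGS-B",
                   bounds=[(0.0, None)] * K,
                   options={"maxiter": maxiter, "gtol": gtol})
    gamma = np.maximum(res.x, 0.0)
    neg2, beta, XtHiX, yPy = profile(gamma)
    sigma_e2 = yPy / (n - p)
    components = {l: float(g * sigma_e2 * scale**2) for l, g in zip(labels, gamma)}
    cov_beta = sigma_e2 * np.linalg.inv(XtHiX) * scale**2
    return LMMFit(beta=beta * scale, cov_beta=cov_beta,
                  components=components,
                  residual=float(sigma_e2 * scale**2),
                  converged=bool(res.success), neg2_reml=float(neg2),
                  n_obs=n, dropped_terms=dropped, message=str(res.message))


def balanced_anova_components(
    y: np.ndarray,
    factors: Sequence[str],
    clip: bool = True,
) -> dict:
    """Expected-mean-squares variance-component estimates for a balanced,
    fully crossed random-effects design.

    ``y`` is an array whose first ``len(factors)`` axes index the factor
    levels; an optional trailing axis holds replicates within each cell.
    With one observation per cell the highest-order interaction is aliased
    with the residual: the returned ``"residual"`` is then their sum and the
    top interaction is omitted.

    Estimates solve ``E[MS_S] = s2_e + sum_{T >= S} (N / n_T) s2_T`` from the
    highest-order terms downward. Negative solutions are truncated at zero
    when ``clip`` is set (the default); pass ``clip=False`` to obtain the raw
    unbiased method-of-moments values.
    """
    y = np.asarray(y, dtype=float)
    k = len(factors)
    if y.ndim == k:
        has_reps = False
    elif y.ndim == k + 1:
        has_reps = True
    else:
        raise IdentifiabilityError(
            f"array of ndim {y.ndim} does not match {k} factors (+ optional reps)"
        )
    levels = y.shape[:k]
    if any(a < 2 for a in levels):
        raise IdentifiabilityError("every factor needs at least 2 levels")
    N = y.size
    all_axes = tuple(range(y.ndim))

    subsets = []
    for r in range(1, k + 1):
        subsets.extend(combinations(range(k), r))

    means = {(): np.mean(y)}
    for S in subsets:
        axes = tuple(a for a in all_axes if a not in S)
        means[S] = y.mean(axis=axes, keepdims=True)

    ms = {}
    df = {}
    for S in subsets:
        effect = np.zeros_like(means[S])
        for r in range(len(S) + 1):
            for U in combinations(S, r):
                effect = effect + (-1) ** (len(S) - len(U)) * means[U]
        n_S = int(np.prod([levels[i] for i in S]))
        ss = (N / n_S) * float(np.sum(effect**2))
        df_S = int(np.prod([levels[i] - 1 for i in S]))
        ms[S] = ss / df_S
        df[S] = df_S

    full = tuple(range(k))
    if has_reps:
        cell_mean = y.mean(axis=-1, keepdims=True)
        ss_e = float(np.sum((y - cell_mean) ** 2))
        df_e = N - int(np.prod(levels))
        if df_e == 0:
            raise IdentifiabilityError("replicate axis has a single replicate")
        sigma_e2 = ss_e / df_e
        estimable = subsets
    else:
        sigma_e2 = ms[full]          # residual + top interaction, lumped
        estimable = [S for S in subsets if S != full]

    est: dict = {}
    for S in sorted(estimable, key=len, reverse=True):
        n_S = int(np.prod([levels[i] for i in S]))
        excess = ms[S] - sigma_e2
        for T in estimable:
            if len(T) > len(S) and set(S) <= set(T):
                n_T = int(np.prod([levels[i] for i in T]))
                excess -= (N / n_T) * est[T]
        est[S] = excess / (N / n_S)

    out = {"×".join(factors[i] for i in S): (max(v, 0.0) if clip else v)
           for S, v in est.items()}
    out["residual"] = sigma_e2
    return out
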