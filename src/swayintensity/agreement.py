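"""PT-versus-alternative rating agreement: pairing, contingency tables,
difference statistics, trial-variance comparison, and linear prediction.

The comparison rating (self-rating or a kinematics-predicted rating) is
joined to every PT rating for the same participant-exercise(-trial), so a
single self-rating is paired with each of that participant's 3-5 PT raters.
Differences are always oriented PT minus other: a positive mean means the
comparison mode under-rates intensity relative to the expert.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateDataError, EmptyJoinError, InputValidationError,
                     InsufficientDataError, UndefinedStatisticError)
from .kinematics import FEATURE_NAMES
from .varcomp import fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "pair_ratings",
    "contingency_table",
    "agreement_by_level",
    "rating_difference_summary",
    "trial_variance_comparison",
    "round_rating",
    "predict_ratings_linear",
    "self_prediction",
    "kinematics_prediction",
]

RATING_LEVELS = (1, 2, 3, 4, 5)


@dataclass
class ContingencyTable:
    """5x5 counts indexed (comparison rating, PT rating), labels 1-5."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(RATING_LEVELS, name="other"),
                            columns=pd.Index(RATING_LEVELS, name="pt"))


def _level_mask(df: pd.DataFrame, level: str) -> pd.Series:
    if level == "trial":
        return df["trial"].notna()
    if level == "exercise":
        return df["trial"].isna()
    raise ValueError(f"level must be 'trial' or 'exercise', got {level!r}")


def pair_ratings(pt_ratings: pd.DataFrame, other_ratings: pd.DataFrame,
                 level: str = "trial") -> pd.DataFrame:
    """One row per PT rating matched to the comparison rating for the same
    participant-exercise(-trial). Unmatched PT ratings are dropped (counted
    in the log); an empty result raises."""
    keys = ["participant_id", "exercise_id"]
    if level == "trial":
        keys.append("trial")
    pt = pt_ratings[_level_mask(pt_ratings, level)]
    other = other_ratings[_level_mask(other_ratings, level)]
    pairs = pt.merge(
        other[keys + ["rating"]].rename(columns={"rating": "other_rating"}),
        on=keys, how="inner")
    dropped = len(pt) - len(pairs)
    if dropped:
        logger.info("dropped %d PT ratings without a matching comparison rating",
                    dropped)
    if len(pairs) == 0:
        raise EmptyJoinError("pairing produced zero rows")
    return pairs.rename(columns={"rating": "pt_rating"})


def contingency_table(pairs: pd.DataFrame) -> ContingencyTable:
    if len(pairs) == 0:
        raise InsufficientDataError("no pairs to tabulate")
    counts = np.zeros((5, 5), dtype=int)
    for row in pairs.itertuples(index=False):
        o, p = int(row.other_rating), int(row.pt_rating)
        if not (1 <= o <= 5 and 1 <= p <= 5):
            raise InputValidationError(
                f"rating outside 1-5 in record {row!r}")
        counts[o - 1, p - 1] += 1
    return ContingencyTable(counts)


def agreement_by_level(table: ContingencyTable, level: int) -> float:
    """Fraction of comparison ratings equal to ``level`` whose paired PT
    rating agreed exactly (diagonal / row total)."""
    if level not in RATING_LEVELS:
        raise ValueError(f"rating level must be 1-5, got {level}")
    row = table.counts[level - 1]
    tot = row.sum()
    if tot == 0:
        raise UndefinedStatisticError(f"no comparison ratings at level {level}")
    return float(row[level - 1] / tot)


@dataclass
class DifferenceSummary:
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int
    inference: bool = True


def rating_difference_summary(pairs: pd.DataFrame) -> DifferenceSummary:
    """Mean and SD of PT - other differences; CI and p for the mean from an
    intercept-only mixed model with random intercepts for participant and PT
    rater (the pairs sharing a participant or rater are not independent).

    A single pair yields the point estimate only (no inference).
    """
    if len(pairs) == 0:
        raise InsufficientDataError("no pairs")
    d = (pairs["pt_rating"] - pairs["other_rating"]).to_numpy(dtype=float)
    mean = float(np.mean(d))
    if len(d) == 1:
        return DifferenceSummary(mean, 0.0, math.nan, math.nan, math.nan, 1,
                                 inference=False)
    sd = float(np.std(d, ddof=1))
    terms = {"participant": pairs["participant_id"].to_numpy(),
             "rater": pairs["rater_id"].to_numpy()}
    terms = {k: v for k, v in terms.items() if len(np.unique(v)) >= 2}
    fit = fit_lmm(d, np.ones((len(d), 1)), terms)
    est = float(fit.beta[0])
    se = float(math.sqrt(fit.cov_beta[0, 0]))
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else math.nan
    return DifferenceSummary(mean, sd, est - z * se, est + z * se, float(p),
                             len(d))


@dataclass
class VarianceComparison:
    mean_variance_difference: float       # mean PT - self trial variance
    ci_low: float
    ci_high: float
    p_value: float
    n_exercises: int
    n_excluded: int = 0
    degenerate: bool = False


def trial_variance_comparison(pt_ratings: pd.DataFrame,
                              self_ratings: pd.DataFrame,
                              n_trials: int = 3) -> VarianceComparison:
    """Paired t-test across exercises of PT versus self trial-to-trial rating
    variance.

    For each (participant, exercise): the self variance across its trials,
    and the PT variance across trials per rater averaged over that
    participant's raters. Exercises missing trials on either side are
    excluded (counted); identical spreads everywhere yield a degenerate test.
    """
    pt = pt_ratings[pt_ratings["trial"].notna()]
    self_r = self_ratings[self_ratings["trial"].notna()]
    keys = ["participant_id", "exercise_id"]

    self_var = (self_r.groupby(keys)["rating"]
                .agg(["var", "count"]).rename(columns={"var": "self_var"}))
    pt_var = (pt.groupby(keys + ["rater_id"])["rating"]
              .agg(["var", "count"]))
    complete_pt = pt_var[pt_var["count"] == n_trials]
    pt_mean_var = complete_pt.groupby(keys)["var"].mean().rename("pt_var")

    merged = self_var[self_var["count"] == n_trials][["self_var"]].join(
        pt_mean_var, how="inner").dropna()
    n_excluded = (self_var.index.nunique() - len(merged))
    if len(merged) == 0:
        raise InsufficientDataError("no exercise has complete trials on both sides")
    diff = (merged["pt_var"] - merged["self_var"]).to_numpy(dtype=float)
    mean = float(np.mean(diff))
    n = len(diff)
    if np.all(diff == diff[0]):
        return VarianceComparison(mean, math.nan, math.nan,
                                  1.0 if diff[0] == 0 else math.nan,
                                  n, n_excluded, degenerate=True)
    t_res = stats.ttest_rel(merged["pt_var"], merged["self_var"])
    sem = stats.sem(diff)
    tcrit = stats.t.ppf(0.975, n - 1)
    return VarianceComparison(mean, mean - tcrit * sem, mean + tcrit * sem,
                              float(t_res.pvalue), n, n_excluded)


def round_rating(pred) -> np.ndarray:
    """Round to the nearest integer, halves away from zero, clipped to 1-5."""
    pred = np.asarray(pred, dtype=float)
    rounded = np.sign(pred) * np.floor(np.abs(pred) + 0.5)
    return np.clip(rounded, 1, 5).astype(int)


@dataclass
class PredictionResult:
    predictions: np.ndarray          # rounded, clipped integer ratings
    raw_predictions: np.ndarray
    accuracy: float                  # exact-match fraction against PT ratings
    coefficients: np.ndarray
    n_obs: int
    rank_deficient: bool = False


def predict_ratings_linear(predictors, targets,
                           kfold: int | None = None,
                           seed: int = 0) -> PredictionResult:
    """OLS fit of PT ratings on a covariate table; accuracy after rounding.

    Predictions are rounded half-away-from-zero and clipped to [1, 5];
    accuracy is the fraction of individual PT ratings matched exactly.
    In-sample by default; ``kfold`` switches to k-fold cross-validated
    predictions (rows shuffled with ``seed``).
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(targets)) != 1:
        X = X.T
    y = np.asarray(targets, dtype=float)
    if len(y) == 0:
        raise InsufficientDataError("no target ratings")
    if X.shape[0] != len(y):
        raise ValueError("predictors and targets differ in length")
    Xd = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(Xd)
    deficient = rank < Xd.shape[1]
    if deficient:
        logger.warning("predictor matrix is rank deficient (%d < %d); "
                       "least-squares uses the minimum-norm solution",
                       rank, Xd.shape[1])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    if kfold is None:
        raw = Xd @ coef
    else:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(y))
        raw = np.empty(len(y))
        for fold in np.array_split(idx, kfold):
            train = np.setdiff1d(idx, fold)
            c, *_ = np.linalg.lstsq(Xd[train], y[train], rcond=None)
            raw[fold] = Xd[fold] @ c
    pred = round_rating(raw)
    acc = float(np.mean(pred == y))
    return PredictionResult(pred, raw, acc, coef, len(y), deficient)


def self_prediction(ratings: pd.DataFrame, level: str = "trial",
                    kfold: int | None = None, seed: int = 0):
    """Predict PT ratings from the paired self-rating; returns
    ``(pairs-with-predictions, PredictionResult)``."""
    pt = ratings[ratings["rater_type"] == "pt"]
    self_r = ratings[ratings["rater_type"] == "self"]
    pairs = pair_ratings(pt, self_r, level=level)
    res = predict_ratings_linear(pairs[["other_rating"]].to_numpy(),
                                 pairs["pt_rating"].to_numpy(),
                                 kfold=kfold, seed=seed)
    out = pairs.copy()
    out["predicted"] = res.predictions
    return out, res


def _feature_columns(feature_set: str) -> list:
    if feature_set == "log":
        return [f"log_{n}" for n in FEATURE_NAMES]
    if feature_set == "raw":
        return list(FEATURE_NAMES)
    if feature_set == "both":
        return list(FEATURE_NAMES) + [f"log_{n}" for n in FEATURE_NAMES]
    raise ValueError(f"feature_set must be log|raw|both, got {feature_set!r}")


def kinematics_prediction(ratings: pd.DataFrame, features: pd.DataFrame,
                          level: str = "trial", feature_set: str = "log",
                          per_exercise_mode: str = "concat",
                          kfold: int | None = None, seed: int = 0):
    """Predict PT ratings from kinematic features.

    Per-trial: the trial's feature vector. Per-exercise: the three trials'
    feature vectors concatenated in trial order (``per_exercise_mode=
    "concat"``) or averaged (``"mean"``). Rows with undefined log features
    are excluded with a logged count. Returns ``(pairs-with-predictions,
    PredictionResult)``.
    """
    cols = _feature_columns(feature_set)
    pt = ratings[ratings["rater_type"] == "pt"]
    if level == "trial":
        wide = features[["participant_id", "exercise_id", "trial"] + cols]
        keys = ["participant_id", "exercise_id", "trial"]
        pt_lvl = pt[pt["trial"].notna()]
    elif level == "exercise":
        keys = ["participant_id", "exercise_id"]
        pt_lvl = pt[pt["trial"].isna()]
        if per_exercise_mode == "concat":
            pieces = []
            for t, g in features.groupby("trial"):
                renamed = g[keys + cols].rename(
                    columns={c: f"{c}_t{t}" for c in cols})
                pieces.append(renamed.set_index(keys))
            wide = pd.concat(pieces, axis=1, join="inner").reset_index()
            cols = [c for c in wide.columns if c not in keys]
        elif per_exercise_mode == "mean":
            wide = features.groupby(keys)[cols].mean().reset_index()
        else:
            raise ValueError("per_exercise_mode must be 'concat' or 'mean'")
    else:
        raise ValueError(f"level must be 'trial' or 'exercise', got {level!r}")

    merged = pt_lvl.merge(wide, on=keys, how="inner")
    n_before = len(merged)
    merged = merged.dropna(subset=cols)
    if n_before - len(merged):
        logger.info("excluded %d rows with undefined features",
                    n_before - len(merged))
    if len(merged) == 0:
        raise EmptyJoinError("no PT ratings joined to features")
    res = predict_ratings_linear(merged[cols].to_numpy(),
                                 merged["rating"].to_numpy(),
                                 kfold=kfold, seed=seed)
    out = merged[keys + ["rater_id", "rating"]].rename(
        columns={"rating": "pt_rating"})
    out["other_rating"] = res.predictions
    out["predicted"] = res.predictions
    return out, res
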