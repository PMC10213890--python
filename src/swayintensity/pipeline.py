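"""End-to-end orchestration: generate (or load) -> filter -> featurize ->
reliability -> association -> agreement, from a single configuration.

The report is evaluated in the order the analyses depend on each other: the
expert (PT) ratings are assessed first — inter-rater reliability and the
difficulty regressions establish whether the scale behaves like an intensity
measure — and only then are the alternative assessments (self-ratings,
kinematics-predicted ratings) compared against them. Ratings are treated as
continuous in every parametric analysis. All randomness flows from one root
seed expanded per stage; identical configuration and seed reproduce the
report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (DIFFICULTY_DIMENSIONS, difficulty_regression,
                          feature_rating_correlation, spearman_agreement)
from .agreement import (contingency_table, agreement_by_level,
                        kinematics_prediction, pair_ratings,
                        rating_difference_summary, self_prediction,
                        trial_variance_comparison)
from .errors import SwayIntensityError, InputValidationError
from .io import features_frame, read_dataset, write_dataset, write_features
from .kinematics import FEATURE_NAMES
from .reliability import icc_analysis
from .synthetic import RatingModel, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults mirror the emulated study protocol."""

    seed: int = 0
    input_dir: str | None = None          # load instead of generating
    output_dir: str | None = None
    # generator settings (used when input_dir is None)
    n_participants: int = 10
    rater_pool: int = 8
    raters_per_participant: tuple = (3, 5)
    rating_model: dict = field(default_factory=dict)
    # kinematics settings
    cutoff_hz: float = 3.0
    filter_order: int = 2
    coverage: float = 0.95
    # analysis toggles and options
    run_kinematics: bool = True
    run_reliability: bool = True
    run_association: bool = True
    run_agreement: bool = True
    icc_maxiter: int = 200
    prediction_feature_set: str = "log"
    kfold: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InputValidationError(f"unknown config keys: {sorted(unknown)}")
        if "raters_per_participant" in doc:
            doc["raters_per_participant"] = tuple(doc["raters_per_participant"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["raters_per_participant"] = list(self.raters_per_participant)
        return d


@dataclass
class StudyReport:
    sections: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, **self.sections}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj, nd=10):
    """Stabilize JSON output across runs by rounding away float noise."""
    if isinstance(obj, float):
        return float(round(obj, nd))
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


class StageError(SwayIntensityError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute every enabled stage and assemble the machine-readable report.

    A stage failure aborts the run with a stage-named error; sections already
    computed are persisted to ``output_dir`` (when set) before the error
    propagates.
    """
    sections: dict = {}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                if out_dir:
                    _persist(sections, out_dir)
                raise StageError(name, exc) from exc
            logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)
        return deco

    state: dict = {}

    @stage("data")
    def _data():
        if config.input_dir:
            design, trials, ratings = read_dataset(config.input_dir)
        else:
            model = RatingModel(**{k: (tuple(v) if isinstance(v, list) else v)
                                   for k, v in config.rating_model.items()})
            design, trials, ratings, truth = generate_study(
                seed=config.seed,
                design_kwargs={"n_participants": config.n_participants,
                               "rater_pool": config.rater_pool,
                               "raters_per_participant":
                                   config.raters_per_participant},
                model=model,
                with_sway=config.run_kinematics,
            )
            if out_dir:
                write_dataset(out_dir / "dataset", design, trials,
                              ratings, truth)
        state.update(design=design, trials=trials, ratings=ratings)
        pt = ratings[ratings["rater_type"] == "pt"]
        sections["data"] = {
            "n_trials": design.n_trials,
            "n_participants": len(design.participants),
            "n_pt_ratings_per_trial": int((pt["trial"].notna()).sum()),
            "n_pt_ratings_per_exercise": int((pt["trial"].isna()).sum()),
            "n_self_ratings_per_trial": int(
                ((ratings["rater_type"] == "self")
                 & ratings["trial"].notna()).sum()),
            "n_self_ratings_per_exercise": int(
                ((ratings["rater_type"] == "self")
                 & ratings["trial"].isna()).sum()),
            "active_exercise_minutes_per_participant":
                design.active_exercise_minutes(),
        }

    if config.run_kinematics:
        @stage("kinematics")
        def _kin():
            feats = features_frame(state["trials"], config.cutoff_hz,
                                   config.filter_order, config.coverage)
            state["features"] = feats
            if out_dir:
                write_features(feats, out_dir / "features.csv")
            sections["kinematics"] = {"n_trials_featurized": len(feats)}

    if config.run_reliability:
        @stage("reliability")
        def _rel():
            out = {}
            for level in ("trial", "exercise"):
                icc, vc = icc_analysis(state["ratings"], level=level,
                                       maxiter=config.icc_maxiter)
                out[level] = {
                    "icc": icc.icc,
                    "literal_rater_ratio": icc.literal_rater_ratio,
                    "category": icc.category,
                    "components": vc.components,
                    "residual": vc.residual,
                    "converged": vc.converged,
                    "dropped_terms": list(vc.dropped_terms),
                }
            sections["reliability"] = out

    if config.run_association:
        @stage("association")
        def _assoc():
            design = state["design"]
            ratings = state["ratings"]
            ex_table = design.exercise_table()
            difficulty = []
            for level in ("trial", "exercise"):
                for dim in DIFFICULTY_DIMENSIONS:
                    r = difficulty_regression(ratings, ex_table, dim, level)
                    difficulty.append({"dimension": dim, "level": level,
                                       "estimate": r.estimate,
                                       "ci_low": r.ci_low, "ci_high": r.ci_high,
                                       "p_value": r.p_value})
            out = {"difficulty_regression": difficulty}

            pt = ratings[ratings["rater_type"] == "pt"]
            self_r = ratings[ratings["rater_type"] == "self"]
            pairs = pair_ratings(pt, self_r, level="exercise")
            rho, lo, hi, p = spearman_agreement(pairs["other_rating"],
                                                pairs["pt_rating"])
            out["self_pt_spearman"] = {"rho": rho, "ci_low": lo,
                                       "ci_high": hi, "p_value": p,
                                       "n_pairs": len(pairs)}

            if config.run_kinematics:
                corr = []
                for name in FEATURE_NAMES:
                    for transform in ("none", "log"):
                        c = feature_rating_correlation(
                            ratings, state["features"], name, transform)
                        corr.append({"feature": name, "transform": transform,
                                     "r": c.r, "r_squared": c.r_squared,
                                     "p_value": c.p_value,
                                     "n_excluded": c.n_excluded})
                out["feature_correlation"] = corr
            sections["association"] = out
            if out_dir:
                pd.DataFrame(difficulty).to_csv(
                    out_dir / "difficulty_regression.csv", index=False)
                if config.run_kinematics:
                    pd.DataFrame(out["feature_correlation"]).to_csv(
                        out_dir / "feature_correlation.csv", index=False)

    if config.run_agreement:
        @stage("agreement")
        def _agree():
            ratings = state["ratings"]
            pt = ratings[ratings["rater_type"] == "pt"]
            self_r = ratings[ratings["rater_type"] == "self"]
            out: dict = {"self": {}, "kinematics": {}}

            for level in ("trial", "exercise"):
                pairs = pair_ratings(pt, self_r, level=level)
                table = contingency_table(pairs)
                diff = rating_difference_summary(pairs)
                agree_lv = {}
                for lv in range(1, 6):
                    try:
                        agree_lv[str(lv)] = agreement_by_level(table, lv)
                    except SwayIntensityError:
                        agree_lv[str(lv)] = None
                _, pred = self_prediction(ratings, level=level,
                                          kfold=config.kfold,
                                          seed=config.seed)
                out["self"][level] = {
                    "n_pairs": len(pairs),
                    "contingency": table.counts.tolist(),
                    "agreement_by_level": agree_lv,
                    "mean_diff": diff.mean_diff, "sd_diff": diff.sd_diff,
                    "ci_low": diff.ci_low, "ci_high": diff.ci_high,
                    "p_value": diff.p_value,
                    "prediction_accuracy": pred.accuracy,
                }
                if out_dir:
                    table.to_frame().to_csv(
                        out_dir / f"contingency_self_{level}.csv")

            vc = trial_variance_comparison(pt, self_r)
            out["trial_variance_comparison"] = {
                "mean_variance_difference": vc.mean_variance_difference,
                "ci_low": vc.ci_low, "ci_high": vc.ci_high,
                "p_value": vc.p_value, "n_exercises": vc.n_exercises,
            }

            if config.run_kinematics:
                for level in ("trial", "exercise"):
                    kin_pairs, pred = kinematics_prediction(
                        ratings, state["features"], level=level,
                        feature_set=config.prediction_feature_set,
                        kfold=config.kfold, seed=config.seed)
                    table = contingency_table(kin_pairs)
                    rho, lo, hi, p = spearman_agreement(
                        kin_pairs["predicted"], kin_pairs["pt_rating"])
                    out["kinematics"][level] = {
                        "n_pairs": pred.n_obs,
                        "contingency": table.counts.tolist(),
                        "prediction_accuracy": pred.accuracy,
                        "spearman_rho": rho, "spearman_p": p,
                    }
                    if out_dir:
                        table.to_frame().to_csv(
                            out_dir / f"contingency_kinematics_{level}.csv")
            sections["agreement"] = out

    config_doc = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    sections_clean = _round_floats(sections)
    report = StudyReport(sections=sections_clean, provenance=provenance)
    if out_dir:
        report.to_json(out_dir / "report.json")
    return report


def _persist(sections: dict, out_dir: Path) -> None:
    (out_dir / "partial_report.json").write_text(
        json.dumps(_round_floats(sections), indent=1, sort_keys=True,
                   default=_jsonable))


def validate_inputs(directory) -> list:
    """Schema and sanity checks on a dataset directory; returns findings.

    Never mutates inputs. Each finding is a dict with ``kind`` and
    ``message`` (and ``where`` when a specific row/trial is implicated).
    """
    directory = Path(directory)
    findings: list = []

    def finding(kind, message, where=None):
        f = {"kind": kind, "message": message}
        if where is not None:
            f["where"] = where
        findings.append(f)

    ratings_path = directory / "ratings.csv"
    if not ratings_path.exists():
        finding("missing-file", f"{ratings_path} does not exist")
        return findings
    try:
        ratings = pd.read_csv(ratings_path)
    except OSError as exc:
        raise InputValidationError(f"cannot read {ratings_path}: {exc}") from exc

    required = {"rater_type", "rater_id", "participant_id", "exercise_id",
                "trial", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        finding("schema", f"ratings.csv missing columns {sorted(missing)}")
        return findings
    bad = ratings[~ratings["rating"].isin([1, 2, 3, 4, 5])]
    for idx, row in bad.iterrows():
        finding("range", f"rating {row['rating']} outside 1-5", where=int(idx))
    bad_type = ratings[~ratings["rater_type"].isin(["pt", "self"])]
    for idx, row in bad_type.iterrows():
        finding("schema", f"rater_type {row['rater_type']!r} not pt|self",
                where=int(idx))

    dup = ratings.duplicated(
        subset=["rater_type", "rater_id", "participant_id", "exercise_id",
                "trial"], keep=False)
    if dup.any():
        finding("duplicate", f"{int(dup.sum())} duplicate rating keys")

    trials_path = directory / "trials.csv"
    if trials_path.exists():
        trials = pd.read_csv(trials_path)
        counts = trials.groupby(["participant_id", "exercise_id"])["trial"].count()
        expected = counts.max()
        for key, c in counts.items():
            if c != expected:
                finding("trial-completeness",
                        f"{key} has {c} trials, expected {expected}",
                        where=list(key))

    sway_path = directory / "sway.csv"
    if sway_path.exists():
        sway = pd.read_csv(sway_path)
        if len(sway):
            fs = None
            design_path = directory / "design.json"
            if design_path.exists():
                fs = json.loads(design_path.read_text()).get("sample_rate_hz")
            for key, g in sway.groupby(["participant_id", "exercise_id", "trial"]):
                dt = np.diff(g["time_s"].to_numpy())
                if len(dt) == 0:
                    finding("too-short", "trial has fewer than 2 samples",
                            where=list(key))
                    continue
                nominal = 1.0 / fs if fs else float(np.median(dt))
                if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                    finding("non-uniform-spacing",
                            "sample spacing deviates more than 1% from nominal",
                            where=list(key))
    return findings
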