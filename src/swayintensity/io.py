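"""Delimited-file dataset layout and round-trip readers.

A dataset directory holds plain-text files only:

* ``exercises.csv`` — exercise_id + the four integer difficulty codes
* ``trials.csv`` — one row per (participant_id, exercise_id, trial) slot
* ``sway.csv`` — long-format time series: participant_id, exercise_id,
  trial, time_s, ap_deg, ml_deg (header required)
* ``ratings.csv`` — rater_type (pt|self), rater_id, participant_id,
  exercise_id, trial (empty for per-exercise ratings), rating (1-5)
* ``design.json`` — participants, groups, schedules, rater assignment
* ``truth.json`` — optional generator ground truth for test harnesses
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .kinematics import SwayTrial
from .synthetic import Exercise, StudyDesign

__all__ = ["write_dataset", "read_dataset", "write_features", "read_features"]

RATING_COLUMNS = ["rater_type", "rater_id", "participant_id", "exercise_id",
                  "trial", "rating"]


def write_dataset(directory, design: StudyDesign, trials, ratings: pd.DataFrame,
                  truth: dict | None = None) -> dict:
    """Write a dataset directory; returns the mapping of written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    ex_table = design.exercise_table()
    paths["exercises"] = directory / "exercises.csv"
    ex_table.to_csv(paths["exercises"], index=False)

    paths["trials"] = directory / "trials.csv"
    design.trial_index().to_csv(paths["trials"], index=False)

    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "exercise_id": tr.exercise_id,
            "trial": tr.trial_number,
            "time_s": tr.time_s,
            "ap_deg": tr.ap_deg,
            "ml_deg": tr.ml_deg,
        }))
    paths["sway"] = directory / "sway.csv"
    if frames:
        # %.17g round-trips float64 exactly through text
        pd.concat(frames, ignore_index=True).to_csv(
            paths["sway"], index=False, float_format="%.17g")
    else:
        pd.DataFrame(columns=["participant_id", "exercise_id", "trial",
                              "time_s", "ap_deg", "ml_deg"]).to_csv(
            paths["sway"], index=False)

    paths["ratings"] = directory / "ratings.csv"
    ratings[RATING_COLUMNS].to_csv(paths["ratings"], index=False)

    design_doc = {
        "participants": list(design.participants),
        "groups": dict(design.groups),
        "exercises": {p: [e.exercise_id for e in design.exercises[p]]
                      for p in design.participants},
        "rater_assignment": {p: list(design.rater_assignment[p])
                             for p in design.participants},
        "trials_per_exercise": design.trials_per_exercise,
        "trial_duration_s": design.trial_duration_s,
        "sample_rate_hz": design.sample_rate_hz,
    }
    paths["design"] = directory / "design.json"
    paths["design"].write_text(json.dumps(design_doc, indent=1, sort_keys=True))

    if truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def read_dataset(directory):
    """Read a dataset directory back into ``(design, trials, ratings)``."""
    directory = Path(directory)
    for name in ("exercises.csv", "ratings.csv", "design.json"):
        if not (directory / name).exists():
            raise InputValidationError(f"missing dataset file: {directory / name}")
    ex_table = pd.read_csv(directory / "exercises.csv")
    exercises = {row.exercise_id: Exercise(row.exercise_id, int(row.surface),
                                           int(row.stance), int(row.vision),
                                           int(row.head_movement))
                 for row in ex_table.itertuples(index=False)}
    doc = json.loads((directory / "design.json").read_text())
    design = StudyDesign(
        participants=tuple(doc["participants"]),
        groups=doc["groups"],
        exercises={p: tuple(exercises[eid] for eid in ids)
                   for p, ids in doc["exercises"].items()},
        rater_assignment={p: tuple(r) for p, r in doc["rater_assignment"].items()},
        trials_per_exercise=int(doc["trials_per_exercise"]),
        trial_duration_s=float(doc["trial_duration_s"]),
        sample_rate_hz=float(doc["sample_rate_hz"]),
    )
    ratings = pd.read_csv(directory / "ratings.csv",
                          dtype={"rater_type": str, "rater_id": str,
                                 "participant_id": str, "exercise_id": str})
    ratings["trial"] = ratings["trial"].astype("Int64")
    ratings["rating"] = ratings["rating"].astype(int)

    trials = []
    sway_path = directory / "sway.csv"
    if sway_path.exists():
        # round_trip parsing restores the written float64 values bit-exactly
        sway = pd.read_csv(sway_path, float_precision="round_trip")
        for (p, e, t), g in sway.groupby(
                ["participant_id", "exercise_id", "trial"], sort=True):
            trials.append(SwayTrial(
                participant_id=p, exercise_id=e, trial_number=int(t),
                time_s=g["time_s"].to_numpy(),
                ap_deg=g["ap_deg"].to_numpy(),
                ml_deg=g["ml_deg"].to_numpy(),
                sample_rate_hz=design.sample_rate_hz,
            ))
    return design, trials, ratings


def write_features(features, path) -> Path:
    """Write a feature table (iterable of KinematicFeatures or a DataFrame);
    undefined log values come out as empty fields."""
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        df = pd.DataFrame([f.as_dict() for f in features])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "exercise_id": str})
    df["trial"] = df["trial"].astype(int)
    return df


def features_frame(trials, cutoff_hz: float = 3.0, order: int = 2,
                   coverage: float = 0.95) -> pd.DataFrame:
    """Filter each trial and compute its feature row."""
    from .kinematics import compute_features, filter_sway

    rows = [compute_features(filter_sway(tr, cutoff_hz, order),
                             coverage=coverage).as_dict()
            for tr in trials]
    return pd.DataFrame(rows)
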