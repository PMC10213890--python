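import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from swayintensity.synthetic import (RatingModel, calibrate_self_offset,
                                     generate_ratings, generate_study_design)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design():
    """A compact study: 4 participants, 3 raters each from a pool of 4."""
    return generate_study_design(n_participants=4, rater_pool=4,
                                 raters_per_participant=(3, 3), seed=11)


@pytest.fixture(scope="session")
def small_ratings(small_design):
    return generate_ratings(small_design, RatingModel(), seed=12)


@pytest.fixture(scope="session")
def calibrated_model():
    """Rating model whose discretized mean PT - self difference is 0.35."""
    return calibrate_self_offset(RatingModel(), 0.35)


@pytest.fixture(scope="session")
def default_design():
    return generate_study_design(seed=5)


def make_feature_rating_data(seed, beta=2.0, sd_participant=1.0,
                             sd_noise=np.sqrt(2.0), n_participants=10,
                             n_trials=45):
    """Continuous ratings from a known mixed model: rating = beta*x + b_p + e,
    with x ~ N(0,1). Returns (ratings-frame, features-frame)."""
    rng = np.random.default_rng(seed)
    n = n_participants * n_trials
    x = rng.standard_normal(n)
    b_p = np.repeat(sd_participant * rng.standard_normal(n_participants),
                    n_trials)
    y = beta * x + b_p + sd_noise * rng.standard_normal(n)
    pid = np.repeat([f"P{i:02d}" for i in range(n_participants)], n_trials)
    trial = np.tile(np.arange(1, n_trials + 1), n_participants)
    ratings = pd.DataFrame({
        "rater_type": "pt", "rater_id": "PT1", "participant_id": pid,
        "exercise_id": "e1", "trial": trial, "rating": y,
    })
    features = pd.DataFrame({
        "participant_id": pid, "exercise_id": "e1", "trial": trial, "x": x,
    })
    return ratings, features
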