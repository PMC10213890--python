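"""Generator contracts: design sampling, sway synthesis, rating model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swayintensity.errors import ConfigurationError
from swayintensity.kinematics import compute_features, filter_sway
from swayintensity.synthetic import (DEFAULT_EXCLUSIONS, Exercise, RatingModel,
                                     SwayProfile, exercise_space,
                                     generate_ratings, generate_sinusoid_trial,
                                     generate_study_design,
                                     generate_sway_trial)


class TestStudyDesign:
    def test_default_design_counts(self, default_design):
        d = default_design
        assert d.n_trials == 450
        assert d.active_exercise_minutes() == pytest.approx(22.5)
        assert all(len(d.exercises[p]) == 15 for p in d.participants)
        assert all(3 <= len(d.rater_assignment[p]) <= 5 for p in d.participants)

    def test_excluded_combinations_never_drawn(self, default_design):
        for p in default_design.participants:
            for ex in default_design.exercises[p]:
                assert ex.codes not in DEFAULT_EXCLUSIONS

    def test_exercises_span_difficulty(self, default_design):
        # one exercise per stratum means both tails of the score range appear
        # (the hardest admissible stratum holds scores 9 and 10)
        for p in default_design.participants:
            scores = sorted(sum(e.codes) for e in default_design.exercises[p])
            assert scores[0] <= 5 and scores[-1] >= 9

    def test_forced_rater_assignment(self):
        d = generate_study_design(n_participants=1, rater_pool=3,
                                  raters_per_participant=(3, 3), seed=0)
        assert d.rater_assignment[d.participants[0]] == ("PT1", "PT2", "PT3")

    def test_pool_smaller_than_request_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_study_design(rater_pool=2, raters_per_participant=(3, 5))

    def test_seeded_determinism_and_seed_sensitivity(self):
        a = generate_study_design(seed=42)
        b = generate_study_design(seed=42)
        assert a == b
        differing = 0
        for s in range(20):
            c = generate_study_design(seed=s)
            differing += (c.exercises != a.exercises)
        assert differing >= 19

    def test_exercise_code_validation(self):
        with pytest.raises(ConfigurationError):
            Exercise("bad", surface=3, stance=1, vision=1, head_movement=1)

    def test_admissible_space_size(self):
        assert len(exercise_space()) == 2 * 5 * 2 * 2 - len(DEFAULT_EXCLUSIONS)


class TestSwayGenerator:
    def test_rms_rescale_is_exact(self):
        tr = generate_sway_trial(SwayProfile(1.0, 0.5, 1.0), seed=3)
        ap = tr.ap_deg - tr.ap_deg.mean()
        ml = tr.ml_deg - tr.ml_deg.mean()
        assert np.sqrt(np.mean(ap**2)) == pytest.approx(1.0, abs=1e-6)
        assert np.sqrt(np.mean(ml**2)) == pytest.approx(0.5, abs=1e-6)

    def test_seeded_reproducibility(self):
        a = generate_sway_trial(SwayProfile(1, 1, 1), seed=9)
        b = generate_sway_trial(SwayProfile(1, 1, 1), seed=9)
        assert np.array_equal(a.ap_deg, b.ap_deg)
        assert np.array_equal(a.ml_deg, b.ml_deg)

    def test_axis_symmetry_when_targets_equal(self):
        # same target RMS on both axes: the velocity distributions over seeds
        # must be statistically indistinguishable (the RMS match is exact)
        ap_mv, ml_mv = [], []
        for s in range(100):
            f = compute_features(generate_sway_trial(SwayProfile(1, 1, 1), seed=s))
            ap_mv.append(f.ap_mv)
            ml_mv.append(f.ml_mv)
        assert stats.ks_2samp(ap_mv, ml_mv).pvalue > 0.01

    def test_wider_bandwidth_moves_faster(self):
        mv = {}
        for bw in (0.5, 2.0):
            mv[bw] = np.mean([
                compute_features(generate_sway_trial(SwayProfile(1, 1, bw),
                                                     seed=s)).phi_mv
                for s in range(50)])
        assert mv[2.0] > mv[0.5]

    def test_invalid_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            SwayProfile(np.nan, 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            SwayProfile(1.0, -0.1, 1.0)


class TestSinusoidTrial:
    def test_definition(self):
        tr = generate_sinusoid_trial((2, 0), (0.5, 1.0))
        assert np.max(tr.ap_deg) == pytest.approx(2.0, abs=1e-6)
        assert np.all(tr.ml_deg == 0)

    def test_quadrature_pair_is_unit_circle(self):
        tr = generate_sinusoid_trial((1, 1), (0.5, 0.5), (0, np.pi / 2))
        ap = tr.ap_deg - tr.ap_deg.mean()
        ml = tr.ml_deg - tr.ml_deg.mean()
        assert np.max(np.abs(np.hypot(ap, ml) - 1.0)) < 1e-9

    def test_integer_periods_have_negligible_mean(self):
        tr = generate_sinusoid_trial((1, 1), (0.5, 0.5))  # 15 periods in 30 s
        assert abs(tr.ap_deg.mean()) < 1e-12


class TestRatingModel:
    def test_deterministic_thresholding_with_zero_variances(self, small_design):
        m = RatingModel(intercept=3.2, difficulty_weights=(0, 0, 0, 0),
                        sd_participant=0, sd_rater=0, sd_exercise=0,
                        sd_trial=0, sd_noise=0, self_offset=0)
        r = generate_ratings(small_design, m, seed=0)
        assert (r["rating"] == 3).all()
        assert np.allclose(r["latent"], 3.2)

    def test_rating_counts_per_mode(self, default_design):
        r = generate_ratings(default_design, RatingModel(), seed=1)
        self_r = r[r["rater_type"] == "self"]
        assert len(self_r[self_r["trial"].notna()]) == 450
        assert len(self_r[self_r["trial"].isna()]) == 150
        n_rater_slots = sum(len(default_design.rater_assignment[p])
                            for p in default_design.participants)
        pt = r[r["rater_type"] == "pt"]
        assert len(pt[pt["trial"].notna()]) == n_rater_slots * 45
        assert len(pt[pt["trial"].isna()]) == n_rater_slots * 15

    def test_ratings_in_range_and_keys_unique(self, small_ratings):
        assert small_ratings["rating"].isin([1, 2, 3, 4, 5]).all()
        keys = small_ratings[["rater_type", "rater_id", "participant_id",
                              "exercise_id", "trial"]]
        assert not keys.duplicated().any()

    def test_symmetric_latent_gives_symmetric_marginals(self):
        # latent centered on 3 with symmetric thresholds: the pooled per-trial
        # rating distribution over 100 seeds is symmetric (chi-square GOF,
        # alpha = .01). Only the per-observation noise is kept so the pooled
        # ratings are independent and the chi-square reference is valid.
        m = RatingModel(intercept=3.0, difficulty_weights=(0, 0, 0, 0),
                        sd_participant=0, sd_rater=0, sd_exercise=0,
                        sd_trial=0, sd_noise=1.2, self_offset=0.0,
                        self_trial_sd_scale=1.0)
        design = generate_study_design(n_participants=2, rater_pool=3,
                                       raters_per_participant=(3, 3), seed=0)
        counts = np.zeros(5)
        for s in range(100):
            r = generate_ratings(design, m, seed=s)
            per_trial = r[r["trial"].notna()]
            counts += np.bincount(per_trial["rating"], minlength=6)[1:]
        expected = (counts + counts[::-1]) / 2
        chi2_stat = np.sum((counts - expected) ** 2 / expected)
        # symmetry pairs (1,5) and (2,4) give 2 degrees of freedom
        assert stats.chi2.sf(chi2_stat, df=2) > 0.01

    def test_negative_self_offset_raises_pt_ratings_above_self(self):
        m = RatingModel()  # self_offset = -0.35
        correct_sign = 0
        for s in range(100):
            d = generate_study_design(seed=s)
            r = generate_ratings(d, m, seed=s + 50_000)
            trial = r[r["trial"].notna()]
            pt = trial[trial["rater_type"] == "pt"]
            sf = trial[trial["rater_type"] == "self"]
            merged = pt.merge(sf[["participant_id", "exercise_id", "trial",
                                  "rating"]],
                              on=["participant_id", "exercise_id", "trial"],
                              suffixes=("", "_self"))
            correct_sign += (merged["rating"] - merged["rating_self"]).mean() > 0
        assert correct_sign >= 95

    def test_threshold_validation(self):
        with pytest.raises(ConfigurationError):
            RatingModel(thresholds=(1.5, 1.5, 3.5, 4.5))
        with pytest.raises(ConfigurationError):
            RatingModel(sd_noise=-0.1)

    def test_per_exercise_latent_is_mean_of_trial_latents(self, small_ratings):
        pt = small_ratings[small_ratings["rater_type"] == "pt"]
        key = ["rater_id", "participant_id", "exercise_id"]
        trial_means = (pt[pt["trial"].notna()].groupby(key)["latent"].mean())
        per_ex = pt[pt["trial"].isna()].set_index(key)["latent"]
        aligned = trial_means.reindex(per_ex.index)
        assert np.allclose(aligned.to_numpy(), per_ex.to_numpy())
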