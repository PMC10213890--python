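"""Pairing, contingency, difference and prediction statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swayintensity.agreement import (ContingencyTable, agreement_by_level,
                                     contingency_table, kinematics_prediction,
                                     pair_ratings, predict_ratings_linear,
                                     rating_difference_summary, round_rating,
                                     self_prediction,
                                     trial_variance_comparison)
from swayintensity.errors import (EmptyJoinError, InputValidationError,
                                  UndefinedStatisticError)


def _records(rows):
    df = pd.DataFrame(rows, columns=["rater_type", "rater_id",
                                     "participant_id", "exercise_id", "trial",
                                     "rating"])
    df["trial"] = df["trial"].astype("Int64")
    return df


class TestPairing:
    def test_one_self_rating_pairs_with_every_pt_rater(self):
        pt = _records([("pt", f"PT{i}", "P1", "E1", 1, 4) for i in range(3)])
        sf = _records([("self", "self", "P1", "E1", 1, 3)])
        pairs = pair_ratings(pt, sf, level="trial")
        assert len(pairs) == 3
        assert (pairs["other_rating"] == 3).all()

    def test_disjoint_keys_raise_empty_join(self):
        pt = _records([("pt", "PT1", "P1", "E1", 1, 4)])
        sf = _records([("self", "self", "P1", "E9", 1, 3)])
        with pytest.raises(EmptyJoinError):
            pair_ratings(pt, sf, level="trial")

    def test_exercise_level_pair_count_matches_design(self, small_design,
                                                      small_ratings):
        pt = small_ratings[small_ratings["rater_type"] == "pt"]
        sf = small_ratings[small_ratings["rater_type"] == "self"]
        pairs = pair_ratings(pt, sf, level="exercise")
        expected = sum(len(small_design.rater_assignment[p]) * 15
                       for p in small_design.participants)
        assert len(pairs) == expected


class TestContingency:
    def test_single_cell(self):
        pairs = pd.DataFrame({"pt_rating": [5, 5, 5],
                              "other_rating": [5, 5, 5]})
        table = contingency_table(pairs)
        assert table.counts[4, 4] == 3
        assert table.total == 3

    def test_grand_total_conserved(self, small_ratings):
        pt = small_ratings[small_ratings["rater_type"] == "pt"]
        sf = small_ratings[small_ratings["rater_type"] == "self"]
        pairs = pair_ratings(pt, sf, level="trial")
        assert contingency_table(pairs).total == len(pairs)

    def test_out_of_range_rating_rejected(self):
        pairs = pd.DataFrame({"pt_rating": [6], "other_rating": [1]})
        with pytest.raises(InputValidationError):
            contingency_table(pairs)


class TestAgreementByLevel:
    def test_direct_ratio(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[4] = [0, 0, 0, 1, 3]
        assert agreement_by_level(ContingencyTable(counts), 5) == 0.75

    def test_perfect_agreement_everywhere(self):
        table = ContingencyTable(np.diag([3, 4, 5, 6, 7]))
        for level in range(1, 6):
            assert agreement_by_level(table, level) == 1.0

    def test_empty_row_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            agreement_by_level(ContingencyTable(np.zeros((5, 5), int)), 2)


class TestDifferenceSummary:
    def test_identical_ratings(self):
        pairs = pd.DataFrame({"pt_rating": [3, 4, 2], "other_rating": [3, 4, 2],
                              "participant_id": ["P1", "P1", "P2"],
                              "rater_id": ["PT1", "PT2", "PT1"]})
        res = rating_difference_summary(pairs)
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0

    def test_constant_offset(self):
        pairs = pd.DataFrame({"pt_rating": [3, 4, 5, 2],
                              "other_rating": [2, 3, 4, 1],
                              "participant_id": ["P1", "P1", "P2", "P2"],
                              "rater_id": ["PT1", "PT2", "PT1", "PT2"]})
        res = rating_difference_summary(pairs)
        assert res.mean_diff == 1.0
        assert res.sd_diff == 0.0

    def test_single_pair_gives_point_estimate_only(self):
        pairs = pd.DataFrame({"pt_rating": [4], "other_rating": [3],
                              "participant_id": ["P1"], "rater_id": ["PT1"]})
        res = rating_difference_summary(pairs)
        assert res.mean_diff == 1.0
        assert not res.inference


class TestTrialVarianceComparison:
    @staticmethod
    def _study(pt_trials, self_trials, n_ex=4):
        pt, sf = [], []
        for e in range(n_ex):
            for t, v in enumerate(pt_trials, start=1):
                pt.append(("pt", "PT1", "P1", f"E{e}", t, v))
            for t, v in enumerate(self_trials, start=1):
                sf.append(("self", "self", "P1", f"E{e}", t, v))
        return _records(pt), _records(sf)

    def test_known_variance_difference(self):
        pt, sf = self._study([3, 4, 5], [2, 2, 2])
        res = trial_variance_comparison(pt, sf)
        assert res.mean_variance_difference == pytest.approx(1.0)
        assert res.degenerate  # same difference in every exercise

    def test_identical_sequences_degenerate_with_p_one(self):
        pt, sf = self._study([3, 4, 5], [3, 4, 5])
        res = trial_variance_comparison(pt, sf)
        assert res.mean_variance_difference == 0.0
        assert res.p_value == 1.0

    def test_incomplete_exercises_excluded(self):
        pt, sf = self._study([3, 4, 5], [2, 3, 2])
        sf = sf[~((sf["exercise_id"] == "E0") & (sf["trial"] == 2))]
        res = trial_variance_comparison(pt, sf)
        assert res.n_exercises == 3
        assert res.n_excluded == 1


class TestLinearPrediction:
    def test_perfect_predictor(self):
        y = np.array([1, 2, 3, 4, 5, 3, 2])
        res = predict_ratings_linear(y.astype(float), y)
        assert res.accuracy == 1.0

    def test_constant_predictor_predicts_modal_middle_class(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 6, size=2000)
        res = predict_ratings_linear(np.ones(2000), y)
        # best constant is the mean (3.0), rounding to class 3; accuracy is
        # that class's frequency, about 1/5 for uniform targets
        assert res.accuracy == pytest.approx(np.mean(y == 3), abs=1e-12)
        assert res.accuracy == pytest.approx(0.2, abs=0.03)

    @pytest.mark.parametrize("raw, expected", [
        (3.5, 4), (5.7, 5), (0.2, 1), (2.49, 2), (-1.0, 1), (4.5, 5),
    ])
    def test_rounding_rule(self, raw, expected):
        assert round_rating([raw])[0] == expected

    @given(raw=st.floats(min_value=-50, max_value=50))
    def test_rounding_always_yields_valid_monotone_ratings(self, raw):
        r = round_rating([raw, raw + 1.0])
        assert 1 <= r[0] <= 5
        assert r[0] <= r[1]  # monotone in the raw prediction

    def test_kfold_predictions_out_of_sample(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        y = round_rating(3 + x)
        res_in = predict_ratings_linear(x, y)
        res_cv = predict_ratings_linear(x, y, kfold=5, seed=0)
        assert res_cv.accuracy <= res_in.accuracy + 0.05

    def test_rater_relabeling_leaves_outputs_unchanged(self, small_ratings):
        relabeled = small_ratings.copy()
        mapping = {f"PT{i}": f"RATER_{9 - i}" for i in range(1, 9)}
        relabeled["rater_id"] = relabeled["rater_id"].replace(mapping)
        a = self_prediction(small_ratings, level="trial")[1]
        b = self_prediction(relabeled, level="trial")[1]
        assert a.accuracy == b.accuracy
        pt_a = small_ratings[small_ratings["rater_type"] == "pt"]
        pt_b = relabeled[relabeled["rater_type"] == "pt"]
        sf = small_ratings[small_ratings["rater_type"] == "self"]
        ta = contingency_table(pair_ratings(pt_a, sf, "trial")).counts
        tb = contingency_table(pair_ratings(pt_b, sf, "trial")).counts
        assert np.array_equal(ta, tb)


@pytest.fixture(scope="module")
def features(small_design):
    from swayintensity.io import features_frame
    from swayintensity.synthetic import generate_trials
    trials = generate_trials(small_design, seed=77)
    return features_frame(trials)


class TestKinematicsPrediction:
    def test_trial_level_runs_and_bounds(self, small_ratings, features):
        pairs, res = kinematics_prediction(small_ratings, features,
                                           level="trial")
        assert 0.0 <= res.accuracy <= 1.0
        assert set(pairs["predicted"]) <= {1, 2, 3, 4, 5}

    def test_exercise_level_concat_uses_all_three_trials(self, small_ratings,
                                                         features):
        pairs, res = kinematics_prediction(small_ratings, features,
                                           level="exercise",
                                           per_exercise_mode="concat")
        # 8 log features per trial, three trials, plus intercept
        assert res.coefficients.shape[0] == 25
        assert 0.0 <= res.accuracy <= 1.0

    def test_exercise_level_mean_mode(self, small_ratings, features):
        pairs, res = kinematics_prediction(small_ratings, features,
                                           level="exercise",
                                           per_exercise_mode="mean")
        assert res.coefficients.shape[0] == 9
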