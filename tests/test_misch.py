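"""MiSCH scoring: weights, probabilities, categories, risk flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mischkit as mk
from mischkit.diversity import jsd
from mischkit.misch import (
    CATEGORY_OF_STAGE,
    StageDistanceWeights,
    categorize,
    evaluate_flags,
    flag_high_risk,
    misch_score,
    score_association_anova,
    subject_score,
)

STAGE_ORDER = ["Healthy", "AGA3", "AGA5", "AGA7"]
FAST = {"n_estimators": 50}


def weights_of(values):
    w = pd.Series(values, index=STAGE_ORDER)
    return StageDistanceWeights(w, w / w.max())


class TestStageDistanceWeights:
    def test_hand_computed_two_taxon_cohort(self):
        # two healthy + two AGA7 samples with 2-taxon compositions
        rows = {
            "h1_T": [0.9, 0.1],
            "h2_T": [0.8, 0.2],
            "a1_T": [0.2, 0.8],
            "a2_T": [0.1, 0.9],
            "b1_T": [0.6, 0.4],
            "c1_T": [0.5, 0.5],
        }
        df = pd.DataFrame(rows, index=["t1", "t2"]).T
        table = mk.AbundanceTable(df, "bacteria")
        meta = mk.CohortMetadata(
            pd.DataFrame(
                {
                    "sample_id": list(rows),
                    "subject_id": [s.split("_")[0] for s in rows],
                    "region": ["T"] * 6,
                    "age": [30] * 6,
                    "stage": ["Healthy", "Healthy", "AGA7", "AGA7", "AGA3", "AGA5"],
                }
            )
        )
        w = mk.stage_distance_weights(table, meta)
        expected_d7 = np.mean(
            [jsd(df.loc[h], df.loc[a]) for h in ("h1_T", "h2_T") for a in ("a1_T", "a2_T")]
        )
        assert w.distances["AGA7"] == pytest.approx(expected_d7)
        assert w.distances["Healthy"] == 0.0
        assert w.weights.max() == pytest.approx(1.0)

    def test_default_cohort_distances_monotone(self, study_merged, study_cohort):
        _, _, meta = study_cohort
        w = mk.stage_distance_weights(study_merged, meta)
        d = w.distances
        assert d["AGA3"] < d["AGA5"] < d["AGA7"]

    def test_identical_samples_degenerate(self):
        df = pd.DataFrame(
            [[0.5, 0.5]] * 8,
            index=[f"s{i}" for i in range(8)],
            columns=["t1", "t2"],
        )
        meta = mk.CohortMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(8)],
                    "subject_id": [f"u{i}" for i in range(8)],
                    "region": ["T"] * 8,
                    "age": [30] * 8,
                    "stage": ["Healthy", "Healthy", "AGA3", "AGA3", "AGA5", "AGA5", "AGA7", "AGA7"],
                }
            )
        )
        with pytest.raises(ValueError, match="zero"):
            mk.stage_distance_weights(mk.AbundanceTable(df, "bacteria"), meta)


class TestMischScore:
    def test_pure_healthy_scores_100(self):
        w = weights_of([0.0, 0.4, 0.7, 1.0])
        assert misch_score([1, 0, 0, 0], w) == 100.0

    def test_pure_severe_scores_0(self):
        w = weights_of([0.0, 0.4, 0.7, 1.0])
        assert misch_score([0, 0, 0, 1], w) == 0.0

    def test_uniform_probabilities_hand_value(self):
        # 100 * (1 - 0.25 * (0 + 0.4 + 0.7 + 1.0)) = 100 * (1 - 0.525)
        w = weights_of([0.0, 0.4, 0.7, 1.0])
        assert misch_score([0.25] * 4, w) == pytest.approx(47.5)

    def test_unnormalized_probabilities_rejected(self):
        w = weights_of([0.0, 0.4, 0.7, 1.0])
        with pytest.raises(ValueError, match="sum"):
            misch_score([0.5, 0.5, 0.5, 0.0], w)

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounds_over_random_simplex_and_weights(self, raw_p, raw_w):
        p = np.array(raw_p) / np.sum(raw_p)
        w = np.array([0.0] + sorted(raw_w))
        w = w / w.max()
        score = misch_score(p, pd.Series(w, index=STAGE_ORDER))
        assert 0.0 <= score <= 100.0

    def test_mass_transfer_monotonicity(self):
        w = weights_of([0.0, 0.4, 0.7, 1.0])
        eps = 0.1
        base = np.array([0.25, 0.25, 0.25, 0.25])
        shifted = base + np.array([0, -eps, 0, eps])
        drop = misch_score(base, w) - misch_score(shifted, w)
        assert drop == pytest.approx(100 * eps * (1.0 - 0.4))


class TestCategories:
    @pytest.mark.parametrize(
        "score,category",
        [
            (100, "healthy"),
            (80, "healthy"),
            (75, "mild"),  # boundary belongs to the lower category
            (26, "mild"),
            (25, "moderate"),
            (16, "moderate"),
            (15, "severe"),
            (0, "severe"),
        ],
    )
    def test_upper_closed_boundaries(self, score, category):
        assert categorize(score) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(101)
        with pytest.raises(ValueError):
            categorize(-0.1)


class TestSubjectScore:
    def test_lower_region_wins(self):
        assert subject_score(80.0, 40.0) == 40.0
        assert subject_score(40.0, 80.0) == 40.0

    def test_equal_scores_pass_through(self):
        assert subject_score(55.0, 55.0) == 55.0

    def test_single_region_warns(self):
        with pytest.warns(UserWarning, match="one region"):
            assert subject_score(70.0, None) == 70.0


class TestRiskFlags:
    def test_healthy_with_mild_category_flagged(self):
        flag = flag_high_risk("Healthy", "mild")
        assert flag.flag == "H–A3"
        assert flag.direction == "more-severe"

    def test_aga5_with_severe_category_flagged(self):
        assert flag_high_risk("AGA5", "severe").flag == "A5–A7"

    def test_concordance_not_flagged(self):
        flag = flag_high_risk("AGA3", "mild")
        assert flag.flag is None
        assert flag.direction == "concordant"

    def test_less_severe_direction_recorded(self):
        flag = flag_high_risk("AGA7", "moderate")
        assert flag.flag is None
        assert flag.direction == "less-severe"

    @pytest.mark.parametrize("stage", STAGE_ORDER)
    def test_category_stage_round_trip_concordant(self, stage):
        assert flag_high_risk(stage, CATEGORY_OF_STAGE[stage]).direction == "concordant"


class TestAveragedProbabilities:
    def test_rows_sum_to_one_and_reproducible(self, small_merged, small_cohort):
        _, _, meta = small_cohort
        p1 = mk.averaged_probabilities(
            small_merged, meta, n_repeats=6, seed=4, params=FAST,
            ensure_coverage=True,
        )
        p2 = mk.averaged_probabilities(
            small_merged, meta, n_repeats=6, seed=4, params=FAST,
            ensure_coverage=True,
        )
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_argmax_recovers_stage_on_separated_cohort(
        self, small_merged, small_cohort
    ):
        _, _, meta = small_cohort
        proba = mk.averaged_probabilities(
            small_merged, meta, n_repeats=10, seed=2, params=FAST,
            ensure_coverage=True,
        )
        hit = (proba.idxmax(axis=1) == meta.df["stage"]).mean()
        assert hit >= 0.85


class TestScoreAnova:
    def test_monotone_planted_scores_significant(self):
        rng = np.random.default_rng(0)
        stages = pd.Series(
            ["Healthy"] * 20 + ["AGA3"] * 15 + ["AGA5"] * 10 + ["AGA7"] * 10,
            index=[f"s{i}" for i in range(55)],
        )
        base = stages.map({"Healthy": 85, "AGA3": 55, "AGA5": 20, "AGA7": 8})
        scores = base + rng.normal(0, 5, len(base))
        f, p = score_association_anova(scores.clip(0, 100), stages)
        assert p < 0.01

    def test_identical_scores_zero_f(self):
        stages = pd.Series(["Healthy"] * 3 + ["AGA3"] * 3, index=list("abcdef"))
        scores = pd.Series([50.0] * 6, index=list("abcdef"))
        f, _ = score_association_anova(scores, stages)
        assert f == 0.0

    def test_two_group_textbook_f(self):
        stages = pd.Series(["Healthy"] * 3 + ["AGA3"] * 3, index=list("abcdef"))
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        f, _ = score_association_anova(scores, stages)
        assert f == pytest.approx(13.5)


class TestEvaluateFlags:
    def test_perfect_flags_score_one(self):
        flags = [
            mk.RiskFlag(f"x{i}", "AGA5", "severe", "AGA7", "A5–A7", "more-severe")
            for i in range(3)
        ]
        flags.append(mk.RiskFlag("y0", "AGA5", "moderate", "AGA5", None, "concordant"))
        out = evaluate_flags(flags, ["x0", "x1", "x2"], flag_label="A5–A7")
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0
        assert out["f1"] == 1.0
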