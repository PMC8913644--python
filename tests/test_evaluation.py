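"""Evaluation statistics: accuracy, comparisons, reliability, diversity, bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lba
from lba.datatypes import PredictionResult
from lba.errors import (
    AlignmentError,
    InvalidComparisonError,
    InvalidParameterError,
    UndefinedStatisticError,
)


def _result(y, yhat, name="m"):
    r, p = lba.pearson_r(y, yhat)
    return PredictionResult(
        y_observed=y, y_predicted=yhat,
        fold_assignment=np.zeros(len(y), dtype=int), fold_penalties=(1.0,),
        accuracy_r=r, accuracy_p=p, model_name=name,
    )


class TestPearson:
    def test_identity_and_reflection(self, rng):
        a = rng.normal(size=30)
        assert lba.pearson_r(a, a)[0] == pytest.approx(1.0)
        assert lba.pearson_r(a, -a)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert lba.pearson_r(a, b)[0] == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            lba.pearson_r(np.ones(10), np.arange(10.0))


class TestPairedErrorT:
    def test_identical_models_not_significant(self, rng):
        y = rng.normal(size=50)
        res = _result(y, y + rng.normal(size=50))
        cmp = lba.compare_same_outcome(res, res)
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_constructed_dominance_is_detected(self, rng):
        y = rng.normal(size=100)
        perfect = _result(y, y + 1e-9 * rng.normal(size=100), "truth")
        signs = rng.choice([-1.0, 1.0], size=100)
        worse = _result(y, y + 2.0 * signs, "perturbed")
        cmp = lba.compare_same_outcome(perfect, worse)
        assert cmp.p_value < 0.001

    def test_equal_magnitude_sign_flips_not_significant(self, rng):
        y = rng.normal(size=40)
        signs = rng.choice([-1.0, 1.0], size=40)
        a = _result(y, y + 0.7 * signs)
        b = _result(y, y - 0.7 * signs)
        assert lba.compare_same_outcome(a, b).p_value == pytest.approx(1.0)

    def test_swapping_models_flips_sign_keeps_p(self, rng):
        y = rng.normal(size=60)
        a = _result(y, y + rng.normal(scale=0.5, size=60))
        b = _result(y, y + rng.normal(scale=1.5, size=60))
        ab = lba.compare_same_outcome(a, b)
        ba = lba.compare_same_outcome(b, a)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_different_outcomes_redirected_to_bootstrap(self, rng):
        y1, y2 = rng.normal(size=30), rng.normal(size=30)
        with pytest.raises(InvalidComparisonError, match="bootstrap"):
            lba.compare_same_outcome(_result(y1, y1 + 1), _result(y2, y2 + 1))

    def test_raw_and_squared_transforms_available(self, rng):
        y = rng.normal(size=40)
        a, b = _result(y, y + 0.3), _result(y, y - 0.3)
        for transform in ("raw", "squared", "absolute"):
            cmp = lba.compare_same_outcome(a, b, error_transform=transform)
            assert 0.0 <= cmp.p_value <= 1.0


class TestBootstrapOverlap:
    def test_identical_models_give_p_one(self, rng):
        y = rng.normal(size=40)
        res = _result(y, y + rng.normal(size=40))
        assert lba.compare_bootstrap(res, res, n_boot=200, seed=0).p_value == 1.0

    def test_deterministic_under_seed(self, rng):
        y = rng.normal(size=50)
        a = _result(y, y + rng.normal(size=50))
        b = _result(y, y + rng.normal(scale=2.0, size=50))
        p1 = lba.compare_bootstrap(a, b, n_boot=300, seed=7).p_value
        p2 = lba.compare_bootstrap(a, b, n_boot=300, seed=7).p_value
        assert p1 == p2

    def test_small_n_boot_warns(self, rng):
        y = rng.normal(size=30)
        res = _result(y, y + rng.normal(size=30))
        with pytest.warns(UserWarning, match="n_boot"):
            lba.compare_bootstrap(res, res, n_boot=50, seed=0)

    def test_mismatched_lengths_rejected(self, rng):
        y1, y2 = rng.normal(size=30), rng.normal(size=40)
        with pytest.raises(AlignmentError):
            lba.compare_bootstrap(_result(y1, y1 + 1e-3 * np.arange(30)),
                                  _result(y2, y2 + 1e-3 * np.arange(40)),
                                  n_boot=100, seed=0)


def _scale(items):
    frame = pd.DataFrame(np.asarray(items, dtype=float))
    frame.columns = [f"item_{j+1}" for j in range(frame.shape[1])]
    lo = min(1, int(np.floor(frame.min().min())))
    hi = max(7, int(np.ceil(frame.max().max())))
    return lba.RatingScaleData(items=frame, scale_range=(lo, hi), scale_name="toy")


class TestReliability:
    def test_identical_items_have_unit_reliability(self):
        x = np.tile(np.array([[1.0], [4.0], [7.0], [2.0]]), (1, 3))
        scale = _scale(x)
        assert lba.inter_item_mean(scale) == pytest.approx(1.0)
        assert lba.corrected_item_total_mean(scale) == pytest.approx(1.0)
        assert lba.cronbach_alpha(scale) == pytest.approx(1.0)

    def test_two_item_hand_computed_correlation(self):
        items = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 5.0]])
        expected = np.corrcoef(items[:, 0], items[:, 1])[0, 1]
        assert lba.inter_item_mean(_scale(items)) == pytest.approx(expected, abs=1e-12)

    def test_three_item_hand_computed_item_total(self):
        items = np.array([[1.0, 2.0, 2.0], [2.0, 1.0, 3.0], [3.0, 4.0, 5.0], [4.0, 5.0, 4.0]])
        expected = np.mean([
            np.corrcoef(items[:, j], items.sum(axis=1) - items[:, j])[0, 1]
            for j in range(3)
        ])
        assert lba.corrected_item_total_mean(_scale(items)) == pytest.approx(expected, abs=1e-12)

    def test_independent_items_have_no_reliability(self, rng):
        items = rng.normal(4, 1, size=(5000, 5)).clip(1, 7)
        assert abs(lba.inter_item_mean(_scale(items))) < 0.05
        assert abs(lba.cronbach_alpha(_scale(items))) < 0.1

    def test_constant_item_error_names_the_item(self):
        items = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(UndefinedStatisticError, match="item 1"):
            lba.inter_item_mean(_scale(items))

    def test_alpha_matches_spearman_brown_for_parallel_items(self):
        # oracle: alpha == k*r/(1+(k-1)*r) for parallel items with inter-item r
        lat = lba.generate_latents(4000, 0.0, seed=1)
        loading = np.sqrt(0.6)
        scale = lba.generate_scale_items(lat.hil_latent, 5, loading, (1, 7), seed=2,
                                         discretize=False)
        r_bar = lba.inter_item_mean(scale)
        expected = 5 * r_bar / (1 + 4 * r_bar)
        assert lba.cronbach_alpha(scale) == pytest.approx(expected, abs=0.02)

    def test_item_total_exceeds_inter_item_on_calibrated_scale(self):
        lat = lba.generate_latents(3000, 0.0, seed=3)
        scale = lba.generate_scale_items(lat.hil_latent, 5, np.sqrt(0.76), (1, 7), seed=4)
        assert lba.corrected_item_total_mean(scale) > lba.inter_item_mean(scale)

    def test_reliability_report_bundles_everything(self, small_study):
        report = lba.reliability_report(small_study.items_hil, test_retest=(0.71, 0.77))
        assert -1 <= report.inter_item_mean_r <= 1
        assert report.alpha <= 1
        assert report.test_retest == (0.71, 0.77)
        assert report.ceilings["alpha"] == pytest.approx(report.alpha)


class TestReliabilityCeiling:
    def test_perfect_reliability_gives_unit_ceiling(self):
        assert lba.reliability_ceiling(1.0, convention="paper") == 1.0
        assert lba.reliability_ceiling(1.0, 1.0, convention="classical") == 1.0

    def test_paper_convention_is_the_reliability_itself(self):
        assert lba.reliability_ceiling(0.84, convention="paper") == pytest.approx(0.84)

    def test_classical_convention_is_attenuation_root(self):
        assert lba.reliability_ceiling(0.81, 1.0, convention="classical") == pytest.approx(0.9)

    def test_invalid_reliability_rejected(self):
        with pytest.raises(InvalidParameterError):
            lba.reliability_ceiling(0.0)


class TestDiversityIndex:
    def test_uniform_eight_tokens(self):
        report = lba.diversity_index([[t] for t in "abcdefgh"])
        assert report.entropy_bits == pytest.approx(3.0, abs=1e-12)
        assert report.diversity_index == pytest.approx(8.0, abs=1e-9)

    def test_two_balanced_types(self):
        report = lba.diversity_index([["a", "a", "b", "b"]])
        assert report.diversity_index == pytest.approx(2.0, abs=1e-12)

    def test_half_quarter_quarter(self):
        report = lba.diversity_index([["a", "a", "b", "c"]])
        assert report.entropy_bits == pytest.approx(1.5, abs=1e-12)
        assert report.diversity_index == pytest.approx(2 ** 1.5, abs=1e-9)

    def test_empty_corpus_rejected(self):
        with pytest.raises(lba.errors.InvalidInputError):
            lba.diversity_index([[]])

    def test_tokens_are_normalized_like_the_models_saw_them(self):
        report = lba.diversity_index([["Calm!", "calm", "CALM."]])
        assert report.distinct_tokens == 1
        assert report.diversity_index == pytest.approx(1.0)

    def test_pooling_a_corpus_with_itself_leaves_di_unchanged(self, rng):
        lists = [[f"t{rng.integers(6)}" for _ in range(10)] for _ in range(8)]
        once = lba.diversity_index(lists).diversity_index
        twice = lba.diversity_index(lists + lists).diversity_index
        assert twice == pytest.approx(once, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(0, 9), min_size=1, max_size=60))
    def test_bounds_one_to_distinct_token_count(self, draws):
        report = lba.diversity_index([[f"tok{d}" for d in draws]])
        assert 1.0 - 1e-9 <= report.diversity_index <= report.distinct_tokens + 1e-9


class TestInterpretR:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.85, "very strong"), (0.80, "very strong"),
            (0.79, "strong"), (0.60, "strong"),
            (0.47, "moderate"), (0.40, "moderate"),
            (0.39, "weak"), (0.20, "weak"),
            (0.10, "negligible"), (0.0, "negligible"),
            (-0.85, "very strong"), (-0.25, "weak"),
        ],
    )
    def test_band_labels(self, r, label):
        assert lba.interpret_r(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            lba.interpret_r(1.2)


class TestWordCounts:
    def test_mean_and_sd(self):
        mean, sd = lba.word_count_stats([["a"] * 9, ["a"] * 11])
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(np.std([9, 11], ddof=1))
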