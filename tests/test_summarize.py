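"""Weighting, norms, peak-median extraction and the majority/ratio rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microbeta as mb
from microbeta.summarize import Direction, Status, SummarizeError


def _field(beta):
    beta = np.asarray(beta, float)
    d, _, m, n = beta.shape
    return mb.LocalInteractionField(
        beta, tuple(f"t{i}" for i in range(d)),
        tuple(f"e{a}" for a in range(m)),
        tuple(f"s{k}" for k in range(n)))


class TestWeightCombine:
    def test_one_hot_weight_selects_a_slice(self):
        rng = np.random.default_rng(0)
        field = _field(rng.normal(size=(2, 2, 3, 4)))
        w = mb.SummaryWeights(np.array([0.0, 1.0, 0.0]))
        out = mb.weight_combine(field, w)
        np.testing.assert_array_equal(out, field.beta[:, :, 1, :])

    def test_linear_combination_arithmetic(self):
        beta = np.zeros((1, 1, 2, 1))
        beta[0, 0, 0, 0] = 1.0
        beta[0, 0, 1, 0] = 2.0
        out = mb.weight_combine(_field(beta),
                                mb.SummaryWeights(np.array([2.0, 0.5])))
        assert out[0, 0, 0] == pytest.approx(3.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(SummarizeError):
            mb.SummaryWeights(np.zeros(3))

    def test_length_mismatch_rejected(self):
        field = _field(np.zeros((1, 1, 2, 3)))
        with pytest.raises(SummarizeError):
            mb.weight_combine(field, mb.SummaryWeights(np.ones(5)))


class TestNormSummary:
    def test_three_four_five(self):
        assert mb.norm_summary(np.array([3.0, 4.0]), axis=0) == pytest.approx(5.0)

    def test_zero_tensor_gives_zero(self):
        out = mb.norm_summary(np.zeros((2, 2, 3, 4)), axis=2)
        np.testing.assert_array_equal(out, 0.0)

    def test_ones_over_thirteen_parameters(self):
        field = _field(np.ones((2, 2, 13, 5)))
        out = mb.norm_summary(field, axis=2)
        np.testing.assert_allclose(out, np.sqrt(13.0))

    def test_summary_chain_collapses_to_global_influence(self):
        rng = np.random.default_rng(1)
        field = _field(rng.normal(size=(3, 3, 2, 4)))
        beta_ijk = mb.norm_summary(field, axis=2)           # over parameters
        beta_ij = mb.norm_summary(beta_ijk, axis=2)         # over samples
        assert beta_ij.shape == (3, 3)
        assert (beta_ij >= 0).all()
        # beta_ik over j != i, then beta_i over samples
        mask = ~np.eye(3, dtype=bool)
        beta_ik = np.sqrt((beta_ijk ** 2 * mask[:, :, None]).sum(axis=1))
        beta_i = mb.norm_summary(beta_ik, axis=1)
        assert beta_i.shape == (3,)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-10, 10, allow_nan=False))
    def test_absolute_homogeneity(self, c):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 4))
        np.testing.assert_allclose(mb.norm_summary(c * x, axis=1),
                                   abs(c) * mb.norm_summary(x, axis=1),
                                   atol=1e-9)

    def test_empty_axis_selection_rejected(self):
        with pytest.raises(SummarizeError):
            mb.norm_summary(np.ones((2, 2)), axis=())


class TestBasicSummary:
    @pytest.mark.parametrize("values, stat, expected", [
        ([1.0, 2.0, 3.0], "median", 2.0),
        ([1.0, 2.0, 3.0, 4.0], "median", 2.5),
        ([7.0, 7.0, 7.0], "max", 7.0),
    ])
    def test_standard_statistics(self, values, stat, expected):
        assert mb.basic_summary(np.array(values), stat, axis=0) == expected

    def test_unknown_statistic_rejected(self):
        with pytest.raises(SummarizeError):
            mb.basic_summary(np.ones(3), "mode", axis=0)


class TestPeakMedian:
    def test_degenerate_point_mass(self):
        pk = mb.peak_median(np.full(10, 0.3))
        assert pk.direction is Direction.POSITIVE
        assert pk.M == pytest.approx(0.3)

    def test_sixty_forty_split_is_excluded(self):
        values = np.array([1.0] * 6 + [-1.0] * 4)
        pk = mb.peak_median(values)
        assert pk.direction is Direction.EXCLUDED
        assert pk.support == pytest.approx(0.6)

    def test_dominant_mode_median_beats_the_mean(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(1.0, 0.1, 850),
                                 rng.normal(3.0, 0.1, 150)])
        pk = mb.peak_median(values)
        assert pk.direction is Direction.POSITIVE
        assert abs(pk.M - 1.0) < 0.05
        assert abs(values.mean() - 1.3) < 0.05  # the mean is pulled away

    def test_too_few_nonzero_values_excluded(self):
        pk = mb.peak_median(np.array([0.2, -0.1, 0.0, 0.0, 0.0, 0.0]))
        assert pk.direction is Direction.EXCLUDED
        assert "fewer than" in pk.reason

    def test_zeros_do_not_count_toward_the_majority(self):
        values = np.array([0.0] * 10 + [0.5] * 5)
        pk = mb.peak_median(values)
        assert pk.direction is Direction.POSITIVE
        assert pk.support == 1.0

    def test_unimodal_sample_peak_median_approaches_sample_median(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.8, 0.3, 10_000)
        pk = mb.peak_median(values, majority=0.5)
        assert abs(pk.M - np.median(values)) < 0.02


class TestGlobalBeta:
    def test_unanimous_parameters(self):
        peaks = [mb.PeakSummary(0.5, Direction.POSITIVE, 1.0)] * 3
        value, status = mb.global_beta(peaks)
        assert value == pytest.approx(0.5)
        assert status is Status.DETERMINATE

    def test_ratio_rule_resolves_a_split(self):
        peaks = [mb.PeakSummary(1.0, Direction.POSITIVE, 1.0),
                 mb.PeakSummary(-0.1, Direction.NEGATIVE, 1.0)]
        value, status = mb.global_beta(peaks)
        assert value == pytest.approx(1.0)
        assert status is Status.DETERMINATE

    def test_balanced_opposition_is_indeterminate(self):
        peaks = [mb.PeakSummary(1.0, Direction.POSITIVE, 1.0),
                 mb.PeakSummary(-1.0, Direction.NEGATIVE, 1.0)]
        value, status = mb.global_beta(peaks)
        assert np.isnan(value)
        assert status is Status.INDETERMINATE

    def test_ratio_exactly_two_stays_indeterminate(self):
        peaks = [mb.PeakSummary(1.0, Direction.POSITIVE, 1.0),
                 mb.PeakSummary(-0.5, Direction.NEGATIVE, 1.0)]
        _, status = mb.global_beta(peaks)
        assert status is Status.INDETERMINATE

    def test_no_qualifying_parameter(self):
        peaks = [mb.PeakSummary(np.nan, Direction.EXCLUDED, 0.5)] * 2
        _, status = mb.global_beta(peaks)
        assert status is Status.NO_QUALIFYING_PARAMETER

    def test_invariant_to_parameter_order(self):
        rng = np.random.default_rng(9)
        M = rng.normal(0.2, 1.0, 7)
        peaks = [mb.PeakSummary(v, Direction.POSITIVE if v > 0
                                else Direction.NEGATIVE, 1.0) for v in M]
        base = mb.global_beta(peaks)
        for _ in range(5):
            rng.shuffle(peaks)
            assert mb.global_beta(peaks) == base

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False).filter(lambda v: v != 0),
                    min_size=1, max_size=9))
    def test_lower_majority_never_moves_toward_indeterminate(self, values):
        peaks = [mb.PeakSummary(v, Direction.POSITIVE if v > 0
                                else Direction.NEGATIVE, 1.0) for v in values]
        _, strict = mb.global_beta(peaks, majority=0.8)
        _, loose = mb.global_beta(peaks, majority=0.5)
        rank = {Status.NO_QUALIFYING_PARAMETER: 0, Status.INDETERMINATE: 1,
                Status.DETERMINATE: 2}
        assert rank[loose] >= rank[strict]


class TestSummarizeField:
    def test_summarize_constant_positive_field(self):
        field = _field(np.full((2, 2, 3, 8), 0.4))
        gmat, peaks = mb.summarize_field(field)
        np.testing.assert_allclose(gmat.beta, 0.4)
        assert all(s is Status.DETERMINATE for s in gmat.status.ravel())
        assert len(peaks) == 2 * 2 * 3

    def test_weights_rescale_before_summarizing(self):
        field = _field(np.full((1, 1, 2, 8), 0.5))
        w = mb.SummaryWeights(np.array([2.0, 2.0]))
        gmat, _ = mb.summarize_field(field, weights=w)
        assert gmat.beta[0, 0] == pytest.approx(1.0)
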