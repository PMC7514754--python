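"""Core sample-entropy estimator: distances, counts, tolerance, multiscale."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keepsampen import (
    InsufficientDataError,
    MatchCounts,
    SampEnParams,
    TimeSeries,
    chebyshev_distance,
    coarse_grain,
    count_matches,
    multiscale_entropy,
    sample_entropy,
    tolerance_from_sd,
)

from conftest import brute_force_counts, random_series


class TestChebyshevDistance:
    @pytest.mark.parametrize(
        "v1, v2, expected",
        [
            ([1, 2], [1, 2], 0.0),
            ([1, 2], [2, 4], 2.0),
            ([0, 5, 1], [1, 1, 1], 4.0),
        ],
    )
    def test_direct_evaluation(self, v1, v2, expected):
        assert chebyshev_distance(v1, v2) == expected
        assert chebyshev_distance(v2, v1) == expected  # symmetry

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            chebyshev_distance([1, 2], [1, 2, 3])


class TestCountMatches:
    @pytest.mark.parametrize(
        "values, m, r, B, A",
        [
            ([1, 1, 1, 1], 1, 0.0, 6, 6),
            ([1, 2, 1, 2, 1, 3], 1, 0.5, 8, 4),
            ([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], 2, 0.5, 14, 14),
        ],
    )
    def test_enumerated_examples(self, values, m, r, B, A):
        counts = count_matches(TimeSeries.from_values(values), m, r)
        assert (counts.B_total, counts.A_total) == (B, A)

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            count_matches(TimeSeries.from_values([1, 2, 3]), 2, 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        values=st.lists(
            st.integers(min_value=0, max_value=8).map(lambda v: v / 2.0),
            min_size=6,
            max_size=40,
        ),
        m=st.integers(min_value=1, max_value=3),
        r=st.sampled_from([0.0, 0.25, 0.5, 1.0, 2.0]),
    )
    def test_matches_brute_force_enumeration(self, values, m, r):
        """The vectorized counts equal an independent O(N^2) double loop."""
        if len(values) - m < 2:
            return
        series = TimeSeries.from_values(values)
        counts = count_matches(series, m, r)
        assert (counts.B_total, counts.A_total) == brute_force_counts(values, m, r)
        # longer-template matches imply prefix matches
        assert counts.A_total <= counts.B_total
        # determinism: repeated calls give bit-identical counts
        assert count_matches(series, m, r) == counts


class TestToleranceFromSd:
    def test_population_sd_convention_excludes_missing(self):
        # observed values {1, 3}: population SD = 1 (denominator n, not n-1)
        series = TimeSeries.from_values([1.0, np.nan, 3.0])
        r, sigma = tolerance_from_sd(series, factor=1.0)
        assert sigma == 1.0
        assert r == 1.0

    def test_factor_scales_sigma(self):
        values = np.array([0.0, 2.0, 4.0, 2.0])  # population SD sqrt(2)
        r, sigma = tolerance_from_sd(TimeSeries.from_values(values), 0.15)
        assert sigma == pytest.approx(np.sqrt(2.0))
        assert r == pytest.approx(0.15 * np.sqrt(2.0))

    def test_zero_variance_warns_and_returns_zero(self, caplog):
        with caplog.at_level(logging.WARNING, logger="keepsampen.core"):
            r, sigma = tolerance_from_sd(TimeSeries.from_values([1, 1, 1]), 0.15)
        assert (r, sigma) == (0.0, 0.0)
        assert any("zero-variance" in rec.message for rec in caplog.records)

    def test_fewer_than_two_observed_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            tolerance_from_sd(TimeSeries.from_values([1.0, np.nan]), 0.15)


class TestSampleEntropy:
    def test_constant_series_has_zero_entropy(self):
        params = SampEnParams(m=2, tolerance_mode="absolute", r_value=0.0)
        res = sample_entropy(TimeSeries.from_values([5] * 5), params)
        assert res.entropy == 0.0

    def test_alternating_series_gives_ln2(self):
        params = SampEnParams(m=1, tolerance_mode="absolute", r_value=0.5)
        res = sample_entropy(TimeSeries.from_values([1, 2, 1, 2, 1, 3]), params)
        assert res.entropy == pytest.approx(math.log(2.0))
        assert (res.counts.B_total, res.counts.A_total) == (8, 4)

    def test_no_matches_is_undefined_not_zero_or_inf(self):
        params = SampEnParams(m=2, tolerance_mode="absolute", r_value=0.1)
        res = sample_entropy(TimeSeries.from_values([1, 2, 3, 4]), params)
        assert not res.is_defined
        assert res.entropy is None
        assert res.counts is not None  # counts still reported

    def test_rejects_series_with_missing_values(self, default_params):
        with pytest.raises(ValueError, match="fully observed"):
            sample_entropy(TimeSeries.from_values([1.0, np.nan, 2.0, 1.0]), default_params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        a=st.sampled_from([2.0, -0.5, 4.0, -2.0]),
        b=st.integers(min_value=-5, max_value=5),
    )
    def test_scale_and_shift_invariance(self, seed, a, b):
        """With an SD-factor tolerance, entropy is invariant under x -> a*x + b.

        Integer-valued series and power-of-two scale factors keep every
        intermediate exactly representable, so the counts must be
        bit-identical, not merely close.
        """
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, size=60).astype(float)
        if values.std() == 0:
            return
        params = SampEnParams(m=2, tolerance_mode="sd_factor", r_value=0.2)
        res_x = sample_entropy(TimeSeries.from_values(values), params)
        res_ax = sample_entropy(TimeSeries.from_values(a * values + b), params)
        assert res_x.counts == res_ax.counts
        assert res_x.entropy == res_ax.entropy


class TestCoarseGrain:
    def test_block_means(self):
        out = coarse_grain(TimeSeries.from_values([1, 2, 3, 4]), 2)
        assert out.values.tolist() == [1.5, 3.5]

    def test_scale_one_is_identity(self, rng):
        series = random_series(rng, 20)
        assert coarse_grain(series, 1) is series

    def test_trailing_remainder_dropped(self):
        out = coarse_grain(TimeSeries.from_values([1, 2, 3, 4, 5]), 2)
        assert out.values.tolist() == [1.5, 3.5]

    def test_invalid_scale_rejected(self):
        series = TimeSeries.from_values([1, 2, 3])
        with pytest.raises(ValueError):
            coarse_grain(series, 0)
        with pytest.raises(ValueError):
            coarse_grain(series, 4)


class TestMultiscaleEntropy:
    def test_scale_one_equals_plain_sample_entropy(self, rng, default_params):
        series = random_series(rng, 200)
        [(scale, res)] = multiscale_entropy(series, default_params, [1])
        assert scale == 1
        assert res.entropy == sample_entropy(series, default_params).entropy

    def test_constant_series_zero_at_every_scale(self):
        params = SampEnParams(m=2, tolerance_mode="absolute", r_value=0.0)
        series = TimeSeries.from_values([3.0] * 60)
        for _, res in multiscale_entropy(series, params, [1, 2, 3]):
            assert res.entropy == 0.0

    def test_averaging_reduces_entropy_of_white_noise(self):
        """Block-averaging shrinks the effective variance of iid noise while a
        fixed absolute tolerance stays put, so scale-2 entropy falls below
        scale-1 (Monte-Carlo over 20 seeds)."""
        from keepsampen import SignalSpec, generate_signal

        params = SampEnParams(m=2, tolerance_mode="absolute", r_value=0.15)
        diffs = []
        for seed in range(20):
            series = generate_signal(SignalSpec(kind="iid_gaussian", n=5000, seed=seed))
            results = dict(multiscale_entropy(series, params, [1, 2]))
            diffs.append(results[1].entropy - results[2].entropy)
        assert np.mean(diffs) > 0.1

    def test_infeasible_scale_reported_undefined_others_computed(self, default_params):
        series = TimeSeries.from_values(list(range(10)) * 3)
        results = dict(multiscale_entropy(series, default_params, [1, 30]))
        assert results[1].is_defined
        assert not results[30].is_defined

    def test_tolerance_convention_flag(self, rng):
        """Per-scale tolerance re-derives r from the coarse-grained series."""
        series = random_series(rng, 400)
        params = SampEnParams(m=2, tolerance_mode="sd_factor", r_value=0.15)
        global_r = dict(multiscale_entropy(series, params, [2]))
        per_scale = dict(multiscale_entropy(series, params, [2], tolerance_per_scale=True))
        assert global_r[2].r_used != per_scale[2].r_used


def test_match_counts_invariant_enforced():
    with pytest.raises(ValueError, match="A_total"):
        MatchCounts(B_total=2, A_total=3, n_valid_templates=4)
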