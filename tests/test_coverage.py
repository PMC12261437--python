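"""Coverage profiles: segmentation, fractional counts, logistic probabilities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lrquant import (
    LogisticParams,
    accumulate_counts,
    apply_pseudocount,
    build_profile,
    segment_probabilities,
    segment_transcript,
    start_end_probability,
)
from util_oracles import per_base_segment_counts, weighted_span_probability


@pytest.mark.parametrize(
    "length,bin_width,expected",
    [
        (250, 100, [(0, 100), (100, 200), (200, 250)]),
        (100, 100, [(0, 100)]),
        (1, 100, [(0, 1)]),
        (300, 100, [(0, 100), (100, 200), (200, 300)]),
    ],
)
def test_segmentation_tiles_transcript(length, bin_width, expected):
    segments = segment_transcript(length, bin_width)
    assert segments == expected
    # disjoint, ordered, covering [0, length)
    assert segments[0][0] == 0 and segments[-1][1] == length
    for (_, e), (s, _) in zip(segments, segments[1:]):
        assert e == s


@pytest.mark.parametrize("length,bin_width", [(0, 100), (100, 0), (-5, 10)])
def test_segmentation_rejects_nonpositive(length, bin_width):
    with pytest.raises(ValueError):
        segment_transcript(length, bin_width)


@pytest.mark.parametrize(
    "spans,expected",
    [
        ([(0, 100)], [1.0, 0.0]),
        ([(50, 150)], [0.5, 0.5]),
        ([(0, 100), (0, 100)], [2.0, 0.0]),
        ([(0, 200)], [1.0, 1.0]),
    ],
)
def test_fractional_counts_examples(spans, expected):
    counts, n_aligned = accumulate_counts(200, spans, bin_width=100)
    np.testing.assert_allclose(counts, expected)
    assert n_aligned == len(spans)


def test_span_outside_transcript_rejected():
    with pytest.raises(ValueError):
        accumulate_counts(200, [(150, 250)], bin_width=100)


@given(
    length=st.integers(1, 2000),
    bin_width=st.sampled_from([1, 7, 100, 250]),
    seed=st.integers(0, 10_000),
)
def test_counts_match_per_base_depth_oracle(length, bin_width, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(0, 200))
    starts = rng.integers(0, length, size=n)
    ends = np.minimum(length, starts + 1 + rng.integers(0, length, size=n))
    spans = list(zip(starts.tolist(), ends.tolist()))
    counts, _ = accumulate_counts(length, spans, bin_width)
    np.testing.assert_allclose(
        counts, per_base_segment_counts(length, spans, bin_width), atol=1e-9, rtol=0
    )


@given(length=st.integers(50, 1500), seed=st.integers(0, 10_000))
def test_counts_conserve_aligned_bases(length, seed):
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, length, size=30)
    ends = np.minimum(length, starts + 1 + rng.integers(0, 400, size=30))
    spans = list(zip(starts.tolist(), ends.tolist()))
    counts, _ = accumulate_counts(length, spans, bin_width=100)
    seg_len = np.array([e - s for s, e in segment_transcript(length, 100)])
    assert math.isclose(float(counts @ seg_len), float(sum(e - s for s, e in spans)), rel_tol=1e-12)


class TestPseudocount:
    def test_one_percent_of_aligned_reads(self):
        np.testing.assert_allclose(apply_pseudocount(np.array([0.0, 2.0]), 100), [1.0, 3.0])

    def test_no_reads_no_change(self):
        np.testing.assert_allclose(apply_pseudocount(np.array([0.0, 0.0]), 0), [0.0, 0.0])

    def test_single_segment(self):
        np.testing.assert_allclose(apply_pseudocount(np.array([1.0]), 50), [1.5])


class TestSegmentProbabilities:
    def test_uniform_counts_hit_logistic_midpoint(self):
        np.testing.assert_allclose(
            segment_probabilities(np.array([3.0, 3.0, 3.0])), [0.5, 0.5, 0.5]
        )

    def test_zero_growth_rate_is_flat(self):
        probs = segment_probabilities(np.array([1.0, 5.0, 2.0]), LogisticParams(0.0))
        np.testing.assert_allclose(probs, 0.5)

    def test_closed_form_two_segments(self):
        # counts (1, 3): E=2, delta=(0.5, -0.5), a=2 -> logistic(+-1)
        probs = segment_probabilities(np.array([1.0, 3.0]), LogisticParams(2.0))
        np.testing.assert_allclose(
            probs, [1 / (1 + math.exp(-1)), 1 / (1 + math.exp(1))], rtol=1e-12
        )

    def test_no_coverage_gives_flat_half(self):
        np.testing.assert_allclose(segment_probabilities(np.zeros(4)), 0.5)

    @given(
        counts=st.lists(st.floats(0, 1e4), min_size=2, max_size=12),
        idx=st.integers(0, 11),
        bump=st.floats(0.1, 100),
    )
    def test_raising_a_count_never_raises_its_probability(self, counts, idx, bump):
        counts = np.asarray(counts)
        idx = idx % len(counts)
        before = segment_probabilities(counts)[idx]
        higher = counts.copy()
        higher[idx] += bump
        after = segment_probabilities(higher)[idx]
        assert after <= before + 1e-12

    def test_probs_in_open_unit_interval(self):
        profile = build_profile(0, 550, [(0, 550), (500, 550)], bin_width=100)
        assert np.all(profile.probs > 0) and np.all(profile.probs < 1)


class TestStartEndProbability:
    def make_profile(self, probs, length=300, bin_width=100):
        profile = build_profile(0, length, [], bin_width=bin_width)
        profile.probs = np.asarray(probs, dtype=float)
        return profile

    def test_single_full_segment_identity(self):
        profile = self.make_profile([0.2, 0.7, 0.4])
        assert start_end_probability(profile, (100, 200)) == pytest.approx(0.7)

    def test_two_full_segments_average(self):
        profile = self.make_profile([0.4, 0.6, 0.5])
        assert start_end_probability(profile, (0, 200)) == pytest.approx(0.5)

    def test_partial_segment_weighting(self):
        # full segment at 0.4, half a segment at 0.6: (1*0.4 + 0.5*0.6)/1.5
        profile = self.make_profile([0.4, 0.6, 0.5])
        assert start_end_probability(profile, (0, 150)) == pytest.approx((0.4 + 0.3) / 1.5)

    def test_empty_span_rejected(self):
        profile = self.make_profile([0.4, 0.6, 0.5])
        with pytest.raises(ValueError):
            start_end_probability(profile, (100, 100))

    @given(seed=st.integers(0, 5000))
    def test_zero_growth_rate_makes_every_span_half(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 1500))
        spans = [
            (s, min(length, s + 1 + int(rng.integers(0, 300))))
            for s in rng.integers(0, length, size=20).tolist()
        ]
        profile = build_profile(0, length, spans, bin_width=100, params=LogisticParams(0.0))
        start = int(rng.integers(0, length))
        end = min(length, start + 1 + int(rng.integers(0, 400)))
        assert start_end_probability(profile, (start, end)) == pytest.approx(0.5)

    @given(seed=st.integers(0, 5000))
    def test_matches_brute_force_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 1999))
        spans = [
            (s, min(length, s + 1 + int(rng.integers(0, 500))))
            for s in rng.integers(0, length, size=15).tolist()
        ]
        profile = build_profile(0, length, spans, bin_width=100)
        start = int(rng.integers(0, length))
        end = min(length, start + 1 + int(rng.integers(0, 500)))
        expected = weighted_span_probability(length, 100, profile.probs, (start, end))
        assert start_end_probability(profile, (start, end)) == pytest.approx(expected, abs=1e-12)
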