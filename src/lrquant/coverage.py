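"""Per-transcript coverage profiles and segment assignment probabilities.

A transcript is tiled into disjoint fixed-width segments (default 100 nt, the
last one truncated at the transcript end).  Each retained alignment adds to a
segment the *fraction of the segment* it covers, so a segment's count is the
mean per-base depth contributed over it.  After a stabilising pseudocount of
1% of the number of alignments to the transcript, each segment's relative
deviation from the transcript-wide mean count,

    delta_i = (E(c) - c_i) / E(c),        E(c) = sum_i c_i / K,

is mapped through a logistic function ``p = 1 / (1 + exp(-a * delta_i))``
(growth rate ``a = 2`` by default).  Over-covered segments (c_i > E(c)) get
probability below 1/2, sparse segments above 1/2, so the term rewards read
allocations that even out coverage.  The profile is computed once from all
retained alignments and held fixed during inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_alignments import AlignmentRecord, ReadGroup, TranscriptCatalog

DEFAULT_BIN_WIDTH = 100
PSEUDOCOUNT_RATE = 0.01  # 1% of reads aligned to the transcript, per segment


@dataclass(frozen=True)
class LogisticParams:
    """Growth rate of the logistic map from coverage deviation to probability."""

    growth_rate: float = 2.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.growth_rate) or self.growth_rate < 0:
            raise ValueError("growth_rate must be finite and >= 0")


@dataclass
class CoverageProfile:
    """Binned fractional coverage counts and segment probabilities for one transcript."""

    transcript_index: int
    length: int
    bin_width: int
    counts: np.ndarray  # after pseudocount
    probs: np.ndarray  # each in (0, 1)
    n_aligned: float

    @property
    def n_segments(self) -> int:
        return len(self.counts)

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        return segment_transcript(self.length, self.bin_width)


def segment_transcript(length: int, bin_width: int = DEFAULT_BIN_WIDTH) -> list[tuple[int, int]]:
    """Tile ``[0, length)`` into ``ceil(length / bin_width)`` disjoint intervals."""
    if length < 1 or bin_width < 1:
        raise ValueError("length and bin_width must be >= 1")
    bounds = []
    for start in range(0, length, bin_width):
        bounds.append((start, min(start + bin_width, length)))
    return bounds


def _segment_lengths(length: int, bin_width: int) -> np.ndarray:
    n_seg = -(-length // bin_width)
    seg_len = np.full(n_seg, bin_width, dtype=float)
    rem = length - (n_seg - 1) * bin_width
    seg_len[-1] = rem
    return seg_len


def accumulate_counts(
    length: int,
    spans: Iterable[tuple[int, int]],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> tuple[np.ndarray, int]:
    """Fractional segment counts for a set of aligned spans on one transcript.

    Returns ``(counts, n_aligned)`` where ``counts[i]`` sums, over alignments,
    the overlapped fraction of segment ``i`` (overlap length / segment length),
    and ``n_aligned`` is the number of alignments accumulated.
    """
    seg_len = _segment_lengths(length, bin_width)
    counts = np.zeros(len(seg_len))
    n_aligned = 0
    for start, end in spans:
        if not 0 <= start < end <= length:
            raise ValueError(f"span [{start}, {end}) outside transcript of length {length}")
        first = start // bin_width
        last = (end - 1) // bin_width
        for b in range(first, last + 1):
            seg_start = b * bin_width
            seg_end = min(seg_start + bin_width, length)
            overlap = min(end, seg_end) - max(start, seg_start)
            counts[b] += overlap / (seg_end - seg_start)
        n_aligned += 1
    return counts, n_aligned


def apply_pseudocount(counts: np.ndarray, n_aligned: float) -> np.ndarray:
    """Add 1% of the transcript's aligned-read total to every segment count."""
    if n_aligned < 0:
        raise ValueError("n_aligned must be >= 0")
    return counts + PSEUDOCOUNT_RATE * n_aligned


def segment_probabilities(
    counts: np.ndarray, params: LogisticParams = LogisticParams()
) -> np.ndarray:
    """Logistic probability per segment from relative coverage deviation.

    With no coverage at all (mean count zero) every deviation is undefined and
    the profile is flat at 1/2, the logistic midpoint.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a non-empty 1-D array")
    expected = counts.mean()
    if expected == 0:
        return np.full(counts.shape, 0.5)
    delta = (expected - counts) / expected
    return 1.0 / (1.0 + np.exp(-params.growth_rate * delta))


def build_profile(
    transcript_index: int,
    length: int,
    spans: Iterable[tuple[int, int]],
    bin_width: int = DEFAULT_BIN_WIDTH,
    params: LogisticParams = LogisticParams(),
) -> CoverageProfile:
    """Compose segmentation, fractional counting, pseudocount and logistic map."""
    raw, n_aligned = accumulate_counts(length, spans, bin_width)
    counts = apply_pseudocount(raw, n_aligned)
    probs = segment_probabilities(counts, params)
    return CoverageProfile(
        transcript_index=transcript_index,
        length=length,
        bin_width=bin_width,
        counts=counts,
        probs=probs,
        n_aligned=float(n_aligned),
    )


def build_profiles(
    catalog: TranscriptCatalog,
    groups: Sequence[ReadGroup],
    bin_width: int = DEFAULT_BIN_WIDTH,
    params: LogisticParams = LogisticParams(),
) -> list[CoverageProfile]:
    """Build one profile per transcript from all retained alignments.

    Every retained alignment (including every hit of a multimapping read)
    contributes with weight one; the profile is static during inference.
    """
    spans_by_txp: list[list[tuple[int, int]]] = [[] for _ in range(len(catalog))]
    for group in groups:
        for rec in group.alignments:
            spans_by_txp[rec.transcript_index].append((rec.start, rec.end))
    return [
        build_profile(j, catalog.lengths[j], spans_by_txp[j], bin_width, params)
        for j in range(len(catalog))
    ]


def start_end_probability(profile: CoverageProfile, span: tuple[int, int]) -> float:
    """Probability of an alignment's start-end placement given the coverage model.

    Weighted mean of the segment probabilities over the segments the span
    touches; each segment is weighted by the fraction of *the segment* the
    span overlaps, and the weights are normalised to sum to one so the result
    is a convex combination of segment probabilities (hence in (0, 1)).
    """
    start, end = span
    if not 0 <= start < end <= profile.length:
        raise ValueError(f"span [{start}, {end}) outside transcript of length {profile.length}")
    w = profile.bin_width
    first = start // w
    last = (end - 1) // w
    weights = np.empty(last - first + 1)
    for k, b in enumerate(range(first, last + 1)):
        seg_start = b * w
        seg_end = min(seg_start + w, profile.length)
        overlap = min(end, seg_end) - max(start, seg_start)
        weights[k] = overlap / (seg_end - seg_start)
    weights /= weights.sum()
    return float(weights @ profile.probs[first : last + 1])


def profile_table(profile: CoverageProfile) -> list[tuple[int, int, float, float]]:
    """Debug dump rows ``(seg_start, seg_end, count, prob)`` for one transcript."""
    return [
        (s, e, float(c), float(p))
        for (s, e), c, p in zip(profile.segment_bounds, profile.counts, profile.probs)
    ]
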