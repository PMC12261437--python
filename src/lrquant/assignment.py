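"""Fixed conditional probabilities of read-to-transcript alignments.

Each alignment of read ``n`` to transcript ``j`` gets a conditional
probability with two factors, both fixed before inference:

* an alignment-score term ``exp((AS_nj - AS_n^max) / scale)`` relative to the
  read's best score (``scale`` = 10 by default), so the best alignment scores
  exactly 1 and suboptimal alignments fall off exponentially; and
* (coverage variant only) the start-end probability of the aligned span under
  the transcript's coverage profile.

The probability of the read sequence itself given its alignment carries no
read-discriminating information here and is treated as the constant 1; any
per-read constant cancels when responsibilities are normalised in the E-step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .coverage import CoverageProfile, start_end_probability
from .io_alignments import ReadGroup

logger = logging.getLogger(__name__)

ModelVariant = Literal["cov", "nocov"]


@dataclass(frozen=True)
class ScoreParams:
    """Scale (in alignment-score units) of the exponential score falloff."""

    scale: float = 10.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError("scale must be > 0")


@dataclass
class ConditionalProbMatrix:
    """Sparse read x transcript conditional probabilities in CSR layout.

    Row ``n`` holds, for read ``read_ids[n]``, the transcripts it aligns to
    (``txp_idx[indptr[n]:indptr[n+1]]``) and the conditional probability of
    each alignment (``probs`` in the same slots, each in (0, 1]).  Transcripts
    outside a read's alignment set have implicit probability zero.
    """

    read_ids: list[str]
    indptr: np.ndarray
    txp_idx: np.ndarray
    probs: np.ndarray
    n_transcripts: int
    model_variant: ModelVariant
    n_dropped: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def row(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.indptr[n], self.indptr[n + 1]
        return self.txp_idx[lo:hi], self.probs[lo:hi]

    def to_csr(self) -> sp.csr_matrix:
        return sp.csr_matrix(
            (self.probs, self.txp_idx, self.indptr),
            shape=(self.n_reads, self.n_transcripts),
        )


def alignment_score_prob(
    score: int, max_score: int, params: ScoreParams = ScoreParams()
) -> float:
    """Exponential score probability relative to the read's best alignment.

    Equals 1 exactly when ``score == max_score``; invariant to adding any
    constant to both scores.
    """
    if score > max_score:
        raise ValueError(f"score {score} exceeds the read's max score {max_score}")
    return math.exp((score - max_score) / params.scale)


def build_conditionals(
    groups: Iterable[ReadGroup],
    n_transcripts: int,
    variant: ModelVariant = "cov",
    profiles: Sequence[CoverageProfile] | None = None,
    score_params: ScoreParams = ScoreParams(),
) -> ConditionalProbMatrix:
    """Assemble the fixed conditional matrix ``q_nj`` over all read groups.

    ``q_nj`` multiplies the score term with the coverage start-end term
    (``variant="cov"``) or is the score term alone (``variant="nocov"``).
    Reads whose every entry underflows to zero are dropped with a logged count.
    """
    if variant not in ("cov", "nocov"):
        raise ValueError(f"unknown model variant {variant!r}")
    if variant == "cov" and profiles is None:
        raise ValueError("coverage variant requires per-transcript profiles")
    read_ids: list[str] = []
    indptr = [0]
    txp_idx: list[int] = []
    probs: list[float] = []
    n_dropped = 0
    for group in groups:
        max_score = group.max_score
        row_q = []
        for rec in group.alignments:
            q = alignment_score_prob(rec.score, max_score, score_params)
            if variant == "cov":
                assert profiles is not None
                if rec.transcript_index >= len(profiles):
                    raise RuntimeError(
                        f"no coverage profile for transcript index {rec.transcript_index}"
                    )
                q *= start_end_probability(
                    profiles[rec.transcript_index], (rec.start, rec.end)
                )
            row_q.append(q)
        if not any(q > 0 for q in row_q):
            n_dropped += 1
            continue
        for rec, q in zip(group.alignments, row_q):
            if q > 0:
                txp_idx.append(rec.transcript_index)
                probs.append(q)
        read_ids.append(group.read_id)
        indptr.append(len(txp_idx))
    if n_dropped:
        logger.warning("dropped %d reads whose conditional probabilities underflowed", n_dropped)
    return ConditionalProbMatrix(
        read_ids=read_ids,
        indptr=np.asarray(indptr, dtype=np.int64),
        txp_idx=np.asarray(txp_idx, dtype=np.int32),
        probs=np.asarray(probs, dtype=np.float64),
        n_transcripts=n_transcripts,
        model_variant=variant,
        n_dropped=n_dropped,
    )
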