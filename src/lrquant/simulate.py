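"""Synthetic transcriptomes and truncated long-read alignments.

The generator emulates the generative process the quantifier assumes: reads
are sampled i.i.d. across transcripts in proportion to copy number alone (no
length weighting, as long-read protocols lack a fragmentation step), most
reads are shorter than their source transcript, and sequence-identical
regions produce multi-transcript alignments.  Truncation is 3'-anchored: the
alignment end stays at the transcript end while the start moves, mimicking
degradation and early pore exit.  The aligned-length fraction is lognormal
(median 0.65 by default, so transcripts are typically ~1.5x longer than the
aligned reads).

Ambiguity is created by *prefix pairs*: the short transcript of a pair is an
exact prefix of the long one, so every read from the short transcript aligns
to both with (near-)equal score.  Output is a valid name-collated SAM (plus
transcript FASTA and a ground-truth TSV); alignment records are emitted
directly with a full-match CIGAR over the span, since the quantifier consumes
alignments, not base calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io_alignments import AlignmentRecord, ReadGroup, TranscriptCatalog

TRUTH_COLUMNS = ("tname", "true_count", "true_frac")


@dataclass(frozen=True)
class TruncationModel:
    """Read-length model mixing the two truncation mechanisms of long-read data.

    A read is full-length with probability ``p_full``.  Otherwise its aligned
    length is a lognormal fraction of the transcript (median ``median_frac``,
    floored at ``min_len`` nt) and the truncated read is either a 3'-anchored
    degradation/pore-exit product (end fixed at the transcript end, start
    moves) or, with probability ``breakage_frac``, an internal fragment from
    breakage during library preparation or sequencing (both ends move, start
    uniform).  Strictly end-anchored reads stack all their mass on the same
    segments and make the true transcript's own coverage look non-uniform;
    the breakage component spreads read ends the way real libraries do.
    """

    p_full: float = 0.25
    median_frac: float = 0.65
    sigma: float = 0.35
    min_len: int = 50
    breakage_frac: float = 0.5  # share of truncated reads that are internal fragments

    def __post_init__(self) -> None:
        if not 0 <= self.p_full <= 1:
            raise ValueError("p_full must be in [0, 1]")
        if not 0 < self.median_frac <= 1:
            raise ValueError("median_frac must be in (0, 1]")
        if not 0 <= self.breakage_frac <= 1:
            raise ValueError("breakage_frac must be in [0, 1]")


@dataclass(frozen=True)
class ScoreModel:
    """AS = per_base * matched bases - mismatch * mismatched bases + jitter.

    A perfectly matching alignment scores ``per_base`` per base; each
    mismatched base loses the match reward and pays ``mismatch`` on top
    (minimap2-like).  Integer jitter in [-noise, noise] is added per
    alignment so exact ties and near-ties both occur.
    """

    per_base: int = 2
    mismatch: int = 4
    noise: int = 2


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Ambiguity has two sources, mirroring a real transcriptome: *prefix pairs*
    (the short transcript is an exact prefix of the long one; cross-alignments
    tie in score and only coverage can arbitrate) are rare, while *paralog
    pairs* (same-length partners at 1-5% sequence divergence; the
    cross-alignment pays a per-mismatch score penalty) supply the bulk of
    multimapping and are resolvable through the alignment score.
    """

    n_transcripts: int = 50
    length_range: tuple[int, int] = (500, 3000)
    theta: np.ndarray | float | None = 0.5  # simplex vector, or Dirichlet concentration
    n_reads: int = 50_000
    truncation: TruncationModel = field(default_factory=TruncationModel)
    prefix_pairs: list[tuple[int, int]] | None = None  # (short_idx, long_idx); None = auto
    prefix_fraction: float = 0.04  # fraction of transcripts that are prefixes of a partner
    prefix_len_range: tuple[float, float] = (0.4, 0.8)
    paralog_pairs: list[tuple[int, int]] | None = None  # symmetric pairs; None = auto
    paralog_fraction: float = 0.5  # fraction of transcripts with a divergent partner
    paralog_divergence: tuple[float, float] = (0.01, 0.05)
    score: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0


@dataclass
class SimResult:
    catalog: TranscriptCatalog
    theta_true: np.ndarray
    truth_counts: np.ndarray
    read_groups: list[ReadGroup]  # what a round-trip through the SAM should yield
    sam_path: Path
    fasta_path: Path
    truth_path: Path


_BASES = np.array(list("ACGT"))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability ``divergence`` (never to itself)."""
    idx = np.searchsorted(_BASES, np.array(list(seq)))
    hit = rng.random(len(seq)) < divergence
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx[hit] = (idx[hit] + shift) % 4
    return "".join(_BASES[idx])


def _resolve_theta(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    M = config.n_transcripts
    if config.theta is None:
        return np.full(M, 1.0 / M)
    if np.isscalar(config.theta):
        return rng.dirichlet(np.full(M, float(config.theta)))
    theta = np.asarray(config.theta, dtype=float)
    if theta.shape != (M,) or np.any(theta < 0) or not math.isclose(theta.sum(), 1.0):
        raise ValueError("theta must be a length-M vector on the simplex")
    return theta


def _resolve_pairs(
    config: SimConfig, lengths: np.ndarray, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Pick (short, long) prefix pairs and (a, b) paralog pairs on disjoint transcripts.

    Shrinks each prefix short to a fraction of its partner and equalises
    paralog pair lengths (the partner is a mutated same-length copy).
    """
    M = config.n_transcripts
    perm = list(rng.permutation(M))
    used: set[int] = set()

    def take_pairs(explicit, n_auto, kind):
        if explicit is not None:
            pairs = [(int(a), int(b)) for a, b in explicit]
        else:
            pairs = []
            while len(pairs) < n_auto and len(perm) >= 2:
                a, b = int(perm.pop()), int(perm.pop())
                pairs.append((a, b))
            if len(pairs) < n_auto:
                raise ValueError(f"not enough transcripts for {n_auto} {kind} pairs")
        for a, b in pairs:
            if a == b or a in used or b in used:
                raise ValueError(f"{kind} pairs must involve distinct transcripts")
            used.update((a, b))
        return pairs

    n_prefix = int(round(config.prefix_fraction * M))
    n_paralog = int(round(config.paralog_fraction * M / 2))
    prefix_pairs = take_pairs(config.prefix_pairs, n_prefix, "prefix")
    paralog_pairs = take_pairs(config.paralog_pairs, n_paralog, "paralog")
    for short, long_ in prefix_pairs:
        frac = rng.uniform(*config.prefix_len_range)
        lengths[short] = max(1, int(round(frac * lengths[long_])))
    for a, b in paralog_pairs:
        lengths[b] = lengths[a]
    return prefix_pairs, paralog_pairs


def simulate(config: SimConfig, out_dir: str | Path, prefix: str = "sim") -> SimResult:
    """Generate SAM + FASTA + truth TSV under ``out_dir``; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    M = config.n_transcripts
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=M).astype(np.int64)
    prefix_pairs, paralog_pairs = _resolve_pairs(config, lengths, rng)
    short_of = {long_: short for short, long_ in prefix_pairs}
    long_of = {short: long_ for short, long_ in prefix_pairs}
    paralog_of: dict[int, int] = {}
    divergence: dict[int, float] = {}
    for a, b in paralog_pairs:
        paralog_of[a], paralog_of[b] = b, a
        divergence[a] = divergence[b] = float(rng.uniform(*config.paralog_divergence))

    names = tuple(f"T{j + 1}" for j in range(M))
    seqs: list[str] = [""] * M
    derived = set(long_of) | {b for _, b in paralog_pairs}
    for j in range(M):
        if j in derived:
            continue  # prefix shorts are sliced, paralog partners mutated, below
        seqs[j] = "".join(_BASES[rng.integers(0, 4, size=int(lengths[j]))])
    for short, long_ in prefix_pairs:
        seqs[short] = seqs[long_][: int(lengths[short])]
    for a, b in paralog_pairs:
        seqs[b] = _mutate(seqs[a], divergence[a], rng)

    theta = _resolve_theta(config, rng)
    source = rng.choice(M, size=config.n_reads, p=theta)
    truth_counts = np.bincount(source, minlength=M)

    full_mask = rng.random(config.n_reads) < config.truncation.p_full
    breakage_mask = rng.random(config.n_reads) < config.truncation.breakage_frac
    frac = np.exp(
        rng.normal(math.log(config.truncation.median_frac), config.truncation.sigma, config.n_reads)
    )
    frac = np.minimum(frac, 1.0)
    start_frac = rng.random(config.n_reads)  # internal-fragment start, scaled to the slack

    catalog = TranscriptCatalog(names=names, lengths=tuple(int(x) for x in lengths))
    sam_path = out_dir / f"{prefix}.sam"
    fasta_path = out_dir / f"{prefix}.fa"
    truth_path = out_dir / f"{prefix}.truth.tsv"

    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in zip(names, lengths)],
    }
    groups: list[ReadGroup] = []
    noise = config.score.noise
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as af:
        for i in range(config.n_reads):
            j = int(source[i])
            L = int(lengths[j])
            if full_mask[i]:
                read_len = L
            else:
                read_len = int(round(frac[i] * L))
                read_len = max(min(config.truncation.min_len, L), min(read_len, L))
            if full_mask[i] or not breakage_mask[i]:
                start, end = L - read_len, L  # 3'-anchored degradation product
            else:
                start = int(round(start_frac[i] * (L - read_len)))
                end = start + read_len
            # targets: true transcript plus every partner whose sequence carries the span
            targets = [j]
            if j in long_of:  # j is a prefix of long_of[j]; its sequence is shared
                targets.append(long_of[j])
            if j in short_of and end <= lengths[short_of[j]]:
                targets.append(short_of[j])
            if j in paralog_of:  # same-length divergent partner, span always present
                targets.append(paralog_of[j])
            read_id = f"r{i:07d}"
            records = []
            for t in targets:
                if t == paralog_of.get(j):
                    mismatches = int(rng.binomial(read_len, divergence[j]))
                else:
                    mismatches = 0  # prefix partners share the exact sequence
                score = config.score.per_base * read_len - (
                    config.score.per_base + config.score.mismatch
                ) * mismatches
                if noise > 0:
                    score += int(rng.integers(-noise, noise + 1))
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        transcript_index=t,
                        score=score,
                        start=start,
                        end=end,
                    )
                )
            for k, rec in enumerate(records):
                seg = pysam.AlignedSegment(header=af.header)
                seg.query_name = read_id
                seg.flag = 0 if k == 0 else 256  # true transcript primary, partners secondary
                seg.reference_id = rec.transcript_index
                seg.reference_start = rec.start
                seg.mapping_quality = 60 if k == 0 else 0
                seg.cigartuples = [(0, read_len)]
                if k == 0:
                    seg.query_sequence = seqs[j][start:end]
                seg.set_tag("AS", rec.score, value_type="i")
                af.write(seg)
            groups.append(
                ReadGroup(
                    read_id=read_id,
                    alignments=sorted(records, key=lambda r: r.transcript_index),
                )
            )

    with fasta_path.open("w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")

    with truth_path.open("w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for j, name in enumerate(names):
            fh.write(f"{name}\t{int(truth_counts[j])}\t{theta[j]:.6g}\n")

    return SimResult(
        catalog=catalog,
        theta_true=theta,
        truth_counts=truth_counts,
        read_groups=groups,
        sam_path=sam_path,
        fasta_path=fasta_path,
        truth_path=truth_path,
    )


def make_fig1_fixture(
    n_reads: int = 1000, seed: int = 0, out_dir: str | Path = ".", prefix: str = "prefix_pair"
) -> SimResult:
    """Prefix-pair fixture: T2 is an exact prefix (60%) of T1, all reads from T2.

    Every read lies within the shared prefix and aligns to both transcripts
    with equal scores, so only the coverage term can break the tie: T1's
    second "exon" is never covered, while T2 is covered end to end.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    config = SimConfig(
        n_transcripts=2,
        length_range=(1000, 1000),
        theta=np.array([0.0, 1.0]),
        n_reads=n_reads,
        prefix_pairs=[(1, 0)],  # T2 is the prefix of T1
        prefix_len_range=(0.6, 0.6),
        paralog_pairs=[],
        score=ScoreModel(per_base=2, noise=0),
        seed=seed,
    )
    return simulate(config, out_dir, prefix=prefix)
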