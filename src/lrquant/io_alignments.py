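"""Reading and writing of name-collated transcriptome alignments.

Quantification starts from a SAM/BAM file of long reads aligned to a
*transcriptome* (one reference sequence per transcript).  The file must be
collated by query name: all alignment records of one read are contiguous, as
in the default output order of minimap2 or after ``samtools sort -n``.  Every
mapped record must carry the aligner's ``AS`` (alignment score) tag, which is
the only per-alignment quality signal the model consumes.

Coordinates are kept 0-based half-open ``[start, end)`` on transcript
coordinates throughout the package; the aligned span is the reference-consumed
length of the CIGAR, not the read length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Sequence

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .em import AbundanceEstimate

logger = logging.getLogger(__name__)

QUANT_COLUMNS = ("tname", "len", "num_reads", "frac")


class AlignmentFormatError(ValueError):
    """The alignment file violates the input contract (header, tags, flags)."""


class CollationError(AlignmentFormatError):
    """Records of one read are not contiguous in the file."""


@dataclass(frozen=True)
class TranscriptCatalog:
    """Ordered set of transcript names and lengths from the alignment header.

    The position of a transcript in ``names`` is its stable integer index for
    the whole run; all sparse structures downstream refer to transcripts by
    this index.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise AlignmentFormatError("alignment header declares no reference sequences")
        if len(self.names) != len(self.lengths):
            raise AlignmentFormatError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise AlignmentFormatError("duplicate reference names in alignment header")
        if any(length < 1 for length in self.lengths):
            raise AlignmentFormatError("all transcript lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.names)

    @cached_property
    def _index(self) -> dict[str, int]:
        return {name: j for j, name in enumerate(self.names)}

    def index(self, name: str) -> int:
        return self._index[name]


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one read to one transcript."""

    read_id: str
    transcript_index: int
    score: int
    start: int  # 0-based inclusive, transcript coordinates
    end: int  # 0-based exclusive
    is_reverse: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReadGroup:
    """All retained alignments of a single read (its compatibility set)."""

    read_id: str
    alignments: list[AlignmentRecord]

    def __len__(self) -> int:
        return len(self.alignments)

    @property
    def max_score(self) -> int:
        return max(a.score for a in self.alignments)


@dataclass
class StreamStats:
    """Counts of records seen and dropped while streaming an alignment file."""

    reads_seen: int = 0
    reads_yielded: int = 0
    records_seen: int = 0
    records_retained: int = 0
    unmapped_dropped: int = 0
    reverse_dropped: int = 0
    duplicate_collapsed: int = 0
    score_filtered: int = 0


def read_catalog(alignment_file: str | Path) -> TranscriptCatalog:
    """Build a :class:`TranscriptCatalog` from the SAM/BAM ``@SQ`` header."""
    with pysam.AlignmentFile(str(alignment_file), check_sq=False) as af:
        names = tuple(af.references or ())
        lengths = tuple(af.lengths or ())
    return TranscriptCatalog(names=names, lengths=lengths)


def _finalize_group(
    read_id: str,
    records: list[AlignmentRecord],
    min_score_fraction: float | None,
    stats: StreamStats,
) -> ReadGroup | None:
    if not records:
        return None
    # collapse duplicate (read, transcript) hits to the best-scoring one
    best: dict[int, AlignmentRecord] = {}
    for rec in records:
        prev = best.get(rec.transcript_index)
        if prev is None:
            best[rec.transcript_index] = rec
        else:
            stats.duplicate_collapsed += 1
            if rec.score > prev.score:
                best[rec.transcript_index] = rec
    kept = sorted(best.values(), key=lambda r: r.transcript_index)
    if min_score_fraction is not None:
        max_score = max(r.score for r in kept)
        if max_score > 0:
            thresh = min_score_fraction * max_score
            filtered = [r for r in kept if r.score >= thresh]
            stats.score_filtered += len(kept) - len(filtered)
            kept = filtered
    if not kept:
        return None
    stats.records_retained += len(kept)
    stats.reads_yielded += 1
    return ReadGroup(read_id=read_id, alignments=kept)


def stream_read_groups(
    alignment_file: str | Path,
    catalog: TranscriptCatalog | None = None,
    *,
    keep_reverse: bool = False,
    min_score_fraction: float | None = None,
    stats: StreamStats | None = None,
) -> Iterator[ReadGroup]:
    """Yield one :class:`ReadGroup` per read with at least one retained alignment.

    Unmapped records are dropped; reverse-strand alignments are dropped unless
    ``keep_reverse`` (transcriptome references are sense-stranded, so a reverse
    hit is usually spurious unless the protocol sequences cDNA in both
    orientations).  Duplicate hits of a read to the same transcript are
    collapsed to the max-score record.  A mapped record without an ``AS`` tag
    is a format error; a read name that reappears after another read is a
    collation error.
    """
    if stats is None:
        stats = StreamStats()
    with pysam.AlignmentFile(str(alignment_file), check_sq=False) as af:
        if catalog is not None and tuple(af.references or ()) != catalog.names:
            raise AlignmentFormatError("alignment header does not match the supplied catalog")
        lengths = catalog.lengths if catalog is not None else tuple(af.lengths or ())
        finished: set[str] = set()
        current: str | None = None
        buffer: list[AlignmentRecord] = []
        for aln in af:
            name = aln.query_name
            if name is None:
                raise AlignmentFormatError("record without a query name")
            if name != current:
                if current is not None:
                    group = _finalize_group(current, buffer, min_score_fraction, stats)
                    if group is not None:
                        yield group
                    finished.add(current)
                if name in finished:
                    raise CollationError(
                        f"read {name!r} reappears after other reads; input must be "
                        "collated by query name"
                    )
                current = name
                buffer = []
                stats.reads_seen += 1
            stats.records_seen += 1
            if aln.is_unmapped:
                stats.unmapped_dropped += 1
                continue
            if aln.is_reverse and not keep_reverse:
                stats.reverse_dropped += 1
                continue
            if not aln.has_tag("AS"):
                raise AlignmentFormatError(f"mapped record for read {name!r} lacks the AS tag")
            start = aln.reference_start
            end = aln.reference_end  # start + reference-consumed CIGAR length
            if end is None or end <= start:
                raise AlignmentFormatError(f"record for read {name!r} has an empty aligned span")
            tidx = aln.reference_id
            if not 0 <= start < end <= lengths[tidx]:
                raise AlignmentFormatError(
                    f"alignment span [{start}, {end}) outside transcript of length {lengths[tidx]}"
                )
            buffer.append(
                AlignmentRecord(
                    read_id=name,
                    transcript_index=tidx,
                    score=int(aln.get_tag("AS")),
                    start=start,
                    end=end,
                    is_reverse=aln.is_reverse,
                )
            )
        if current is not None:
            group = _finalize_group(current, buffer, min_score_fraction, stats)
            if group is not None:
                yield group
    logger.info(
        "streamed %d reads (%d yielded); dropped %d unmapped, %d reverse, "
        "collapsed %d duplicate records, filtered %d by score fraction",
        stats.reads_seen,
        stats.reads_yielded,
        stats.unmapped_dropped,
        stats.reverse_dropped,
        stats.duplicate_collapsed,
        stats.score_filtered,
    )


def write_quantification(
    estimate: "AbundanceEstimate",
    catalog: TranscriptCatalog,
    out: str | Path,
) -> None:
    """Write the per-transcript estimates as a TSV in catalog order.

    Columns: ``tname`` (transcript), ``len`` (nt), ``num_reads``
    (theta_j * number of assigned reads) and ``frac`` (theta_j itself; the
    model has no effective-length term, so relative abundance equals the
    expected read fraction).
    """
    if len(estimate.theta) != len(catalog):
        raise ValueError(
            f"estimate covers {len(estimate.theta)} transcripts, catalog has {len(catalog)}"
        )
    out = Path(out)
    with out.open("w") as fh:
        fh.write("\t".join(QUANT_COLUMNS) + "\n")
        for j, name in enumerate(catalog.names):
            fh.write(
                f"{name}\t{catalog.lengths[j]}\t{estimate.counts[j]:.6f}\t{estimate.theta[j]:.6g}\n"
            )
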