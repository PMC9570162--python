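"""Basic read alignment: k-mer indexing and maximal exact-match merging.

The reference is indexed once by all of its k-mers (k-mers containing ``N``
are skipped).  Each query is scanned on both orientations: the forward
sequence and its reverse complement.  Every k-mer shared between the scanned
orientation and the reference yields an anchor; anchors that sit on the same
diagonal at consecutive query offsets are merged into one maximal exact-match
segment of length ``run + k - 1``.  Segments shorter than the display
threshold are dropped.

Coordinates are 0-based half-open throughout; reverse-strand segments store
coordinates on the *forward* orientation of the query, with the strand flag
recording that the reference matches the reverse complement of that slice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .errors import ParameterError
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "Strand",
    "KmerIndex",
    "Anchor",
    "MatchSegment",
    "build_kmer_index",
    "scan_anchors",
    "merge_anchors",
    "align_query",
    "DEFAULT_K",
    "RECOMMENDED_K_RANGE",
]

#: Default k-mer size; the sweet spot between sensitivity and speed for
#: genome-scale inputs.
DEFAULT_K = 15

#: k values outside this range work but trigger a warning.
RECOMMENDED_K_RANGE = (10, 50)


class Strand(str, enum.Enum):
    """Match orientation: forward (5'->3', ascending diagonal) or reverse
    (query reverse complement matches the reference, descending diagonal)."""

    FORWARD = "forward"
    REVERSE = "reverse"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Anchor(NamedTuple):
    """A single k-mer exact match before merging."""

    query_pos: int  # 0-based start on the scanned orientation
    ref_pos: int    # 0-based start on the reference
    strand: Strand


@dataclass(frozen=True)
class MatchSegment:
    """One maximal exact match between reference and query.

    ``query_start``/``query_end`` are always on the forward orientation of
    the query.  For ``Strand.REVERSE`` the reference slice equals the reverse
    complement of the query slice.
    """

    query_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: Strand

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def overlaps_ref(self, other: "MatchSegment") -> bool:
        """True if the two segments share any reference base."""
        return self.ref_start < other.ref_end and other.ref_start < self.ref_end


@dataclass(frozen=True)
class KmerIndex:
    """Reference k-mer -> strictly increasing list of 0-based start positions."""

    k: int
    ref_id: str
    ref_length: int
    table: dict[str, list[int]]


def build_kmer_index(ref: SequenceRecord, k: int) -> KmerIndex:
    """Index every k-mer of the reference that contains no ``N``.

    Repeated k-mers keep *all* their positions — repeat regions must show
    every off-diagonal match in the dot plot.
    """
    if k < 1 or k > ref.length:
        raise ParameterError(
            f"k must be in [1, reference length {ref.length}], got {k}"
        )
    seq = ref.seq
    table: dict[str, list[int]] = {}
    # next position at or after i that is an N; windows touching it are skipped
    next_n = _next_n_positions(seq)
    for pos in range(ref.length - k + 1):
        if next_n[pos] < pos + k:
            continue
        table.setdefault(seq[pos : pos + k], []).append(pos)
    return KmerIndex(k=k, ref_id=ref.id, ref_length=ref.length, table=table)


def _next_n_positions(seq: str) -> list[int]:
    """For each index, the smallest j >= index with seq[j] == 'N' (len(seq) if none)."""
    n = len(seq)
    out = [n] * (n + 1)
    nxt = n
    for i in range(n - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


def scan_anchors(
    index: KmerIndex, oriented_query: str, strand: Strand
) -> list[Anchor]:
    """Find every (query k-mer, reference position) match in one orientation.

    The caller passes the forward sequence for ``Strand.FORWARD`` and its
    reverse complement for ``Strand.REVERSE``.  Query k-mers containing ``N``
    yield no anchors.  A query shorter than k yields an empty list.
    """
    k = index.k
    table = index.table
    anchors: list[Anchor] = []
    next_n = _next_n_positions(oriented_query)
    for qpos in range(len(oriented_query) - k + 1):
        if next_n[qpos] < qpos + k:
            continue
        positions = table.get(oriented_query[qpos : qpos + k])
        if positions:
            anchors.extend(Anchor(qpos, rpos, strand) for rpos in positions)
    return anchors


def merge_anchors(
    anchors: Iterable[Anchor],
    k: int,
    query_length: int,
    strand: Strand,
    query_id: str,
) -> list[MatchSegment]:
    """Merge same-diagonal, consecutive anchors into maximal segments.

    Anchors share a diagonal when ``ref_pos - query_pos`` (on the scanned
    orientation) is constant; a run of ``r`` anchors stepping by one base
    spans ``r + k - 1`` bases.  Reverse-strand runs are mapped back to
    forward-query coordinates via ``q_fwd = L - q_scanned_end``.
    """
    by_diag: dict[int, list[int]] = {}
    for a in anchors:
        by_diag.setdefault(a.ref_pos - a.query_pos, []).append(a.query_pos)
    segments: list[MatchSegment] = []
    for diag, qlist in by_diag.items():
        qlist.sort()
        run_start = prev = qlist[0]
        for q in qlist[1:]:
            if q != prev + 1:
                segments.append(
                    _make_segment(run_start, prev + k, diag, strand,
                                  query_length, query_id)
                )
                run_start = q
            prev = q
        segments.append(
            _make_segment(run_start, prev + k, diag, strand,
                          query_length, query_id)
        )
    segments.sort(key=_segment_sort_key)
    return segments


def _make_segment(
    scan_start: int, scan_end: int, diag: int, strand: Strand,
    query_length: int, query_id: str,
) -> MatchSegment:
    if strand is Strand.FORWARD:
        qs, qe = scan_start, scan_end
    else:
        qs, qe = query_length - scan_end, query_length - scan_start
    return MatchSegment(
        query_id=query_id,
        ref_start=scan_start + diag,
        ref_end=scan_end + diag,
        query_start=qs,
        query_end=qe,
        strand=strand,
    )


def _segment_sort_key(seg: MatchSegment):
    return (seg.ref_start, seg.ref_end, seg.strand is Strand.REVERSE,
            seg.query_start)


def align_query(
    index: KmerIndex, query: SequenceRecord, threshold: int | None = None
) -> list[MatchSegment]:
    """Basic alignment of one query: both strands, merged, length-filtered.

    ``threshold`` is the minimum segment length (bp) retained; it defaults to
    k and must be >= k, since no merged segment can be shorter than one
    anchor.
    """
    k = index.k
    if threshold is None:
        threshold = k
    if threshold < k:
        raise ParameterError(
            f"threshold ({threshold}) must be >= k-mer size ({k})"
        )
    segments: list[MatchSegment] = []
    for strand, oriented in (
        (Strand.FORWARD, query.seq),
        (Strand.REVERSE, reverse_complement(query.seq)),
    ):
        anchors = scan_anchors(index, oriented, strand)
        segments.extend(
            merge_anchors(anchors, k, query.length, strand, query.id)
        )
    segments = [s for s in segments if s.length >= threshold]
    segments.sort(key=_segment_sort_key)
    return segments
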