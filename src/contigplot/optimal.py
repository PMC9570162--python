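"""Optimal read alignment: greedy non-overlapping tiling of match segments.

Basic alignment leaves many segments competing for the same reference
region (repeats, both-strand hits, chance k-mer matches).  The optimal step
sweeps the reference left to right: it takes the left-most unresolved
segment, gathers every segment overlapping it on the reference, keeps the
longest of that conflict set, discards everything overlapping the winner,
and repeats.  The result is a set of segments pairwise disjoint on the
reference — the single best explanation of each reference region.

Ties on length break deterministically: smallest ref_start, then forward
strand, then smallest query_start.  Losers are removed whole, never trimmed.
Only reference-axis overlap is resolved; kept segments may overlap on the
query axis.

:func:`select_optimal` tiles the segments of one query.  :func:`tile_jointly`
runs the identical greedy rule on the pooled segments of *all* queries, so
that a chance short match from one query cannot claim a reference region that
another query explains with a long segment; the full pipeline uses the joint
form.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError, UsageError
from .kmer_align import MatchSegment, Strand
from .seqio import SequenceRecord, reverse_complement

__all__ = ["Tiling", "select_optimal", "tile_jointly", "assemble_optimal_sequence"]


@dataclass(frozen=True)
class Tiling:
    """A reference-disjoint selection of one query's match segments."""

    query_id: str
    segments: tuple[MatchSegment, ...]  # sorted by ref_start
    mapped_bases: int

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.ref_start < a.ref_end:
                raise ConsistencyError(
                    f"tiling segments overlap on reference: {a} / {b}"
                )
        if self.mapped_bases != sum(s.length for s in self.segments):
            raise ConsistencyError("mapped_bases does not equal sum of lengths")


def _preference(seg: MatchSegment):
    # larger length wins; then smaller ref_start, forward strand, smaller query_start
    return (-seg.length, seg.ref_start, seg.strand is Strand.REVERSE,
            seg.query_start)


def _sweep_order(seg: MatchSegment):
    return (seg.ref_start, seg.ref_end, seg.strand is Strand.REVERSE,
            seg.query_start)


def _greedy_tiling(segments: list[MatchSegment]) -> list[MatchSegment]:
    remaining = sorted(segments, key=_sweep_order)
    kept: list[MatchSegment] = []
    while remaining:
        opener = remaining[0]
        conflict = [s for s in remaining if s.overlaps_ref(opener)]
        winner = min(conflict, key=_preference)
        kept.append(winner)
        remaining = [s for s in remaining if not s.overlaps_ref(winner)]
    kept.sort(key=_sweep_order)
    return kept


def select_optimal(segments: list[MatchSegment]) -> Tiling:
    """Greedy reference-axis tiling of one query's segments.

    All segments must carry the same query id; mixed input is a usage error.
    Returns a :class:`Tiling` whose segments are pairwise disjoint on the
    reference, sorted by ref_start.
    """
    ids = {s.query_id for s in segments}
    if len(ids) > 1:
        raise UsageError(f"select_optimal expects one query id, got {sorted(ids)}")
    kept = _greedy_tiling(segments)
    return Tiling(
        query_id=ids.pop() if ids else "",
        segments=tuple(kept),
        mapped_bases=sum(s.length for s in kept),
    )


def tile_jointly(segments: list[MatchSegment]) -> dict[str, Tiling]:
    """Run the greedy tiling on the pooled segments of all queries at once.

    Conflicts are resolved purely on the reference axis regardless of which
    query a segment belongs to; the kept segments are then regrouped into one
    :class:`Tiling` per query id (queries that keep nothing get an empty
    tiling only if they appeared in the input).
    """
    kept = _greedy_tiling(segments)
    ids = {s.query_id for s in segments}
    per_query: dict[str, list[MatchSegment]] = {qid: [] for qid in ids}
    for seg in kept:
        per_query[seg.query_id].append(seg)
    return {
        qid: Tiling(
            query_id=qid,
            segments=tuple(segs),
            mapped_bases=sum(s.length for s in segs),
        )
        for qid, segs in per_query.items()
    }


def assemble_optimal_sequence(
    tiling: Tiling, query: SequenceRecord
) -> list[tuple[int, int, str]]:
    """Emit the tiled query slices in reference order.

    One ``(ref_start, original_query_start, subsequence)`` entry per tiling
    segment, positions 1-based.  Reverse-strand slices are reverse
    complemented so that concatenating the subsequences follows the reference
    orientation.
    """
    out: list[tuple[int, int, str]] = []
    for seg in tiling.segments:
        if seg.query_id != query.id:
            raise ConsistencyError(
                f"tiling for {tiling.query_id!r} does not match query {query.id!r}"
            )
        if seg.query_end > query.length or seg.query_start < 0:
            raise ConsistencyError(f"segment out of query bounds: {seg}")
        sub = query.seq[seg.query_start : seg.query_end]
        if seg.strand is Strand.REVERSE:
            sub = reverse_complement(sub)
        out.append((seg.ref_start + 1, seg.query_start + 1, sub))
    return out
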