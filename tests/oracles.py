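"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the package's k-mer/anchor machinery: exact matches
are found by direct base-by-base diagonal comparison, and the tiling oracle
is a naive best-first list scan.
"""

from __future__ import annotations

import numpy as np

from contigplot.kmer_align import MatchSegment, Strand
from contigplot.seqio import reverse_complement


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _diagonal_runs(ref: np.ndarray, scanned: np.ndarray, min_len: int):
    """Yield (ref_start, scan_start, length) maximal base-match runs.

    A run is a maximal stretch of positions where ref and the scanned
    orientation agree and neither base is N ('N' never matches anything,
    itself included).
    """
    n_code = ord("N")
    for d in range(-(len(scanned) - 1), len(ref)):
        q0 = max(0, -d)
        r0 = q0 + d
        span = min(len(scanned) - q0, len(ref) - r0)
        if span < min_len:
            continue
        eq = (ref[r0 : r0 + span] == scanned[q0 : q0 + span]) \
            & (ref[r0 : r0 + span] != n_code)
        # run-length extraction over the boolean diagonal
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= min_len:
                yield r0 + int(start), q0 + int(start), int(stop - start)


def brute_force_mems(
    ref_seq: str, query_seq: str, query_id: str, min_len: int
) -> set[tuple]:
    """All maximal exact matches of length >= min_len, both strands.

    Returned as hashable tuples (ref_start, ref_end, query_start, query_end,
    strand) with query coordinates on the forward orientation.
    """
    ref = _encode(ref_seq)
    out: set[tuple] = set()
    for strand, scanned_seq in (
        (Strand.FORWARD, query_seq),
        (Strand.REVERSE, reverse_complement(query_seq)),
    ):
        scanned = _encode(scanned_seq)
        L = len(scanned_seq)
        for r0, s0, length in _diagonal_runs(ref, scanned, min_len):
            if strand is Strand.FORWARD:
                qs, qe = s0, s0 + length
            else:
                qs, qe = L - (s0 + length), L - s0
            out.add((r0, r0 + length, qs, qe, strand))
    return out


def segment_key(seg: MatchSegment) -> tuple:
    return (seg.ref_start, seg.ref_end, seg.query_start, seg.query_end,
            seg.strand)


def best_first_tiling(segments: list[MatchSegment]) -> list[MatchSegment]:
    """Naive conflict-resolution oracle.

    Repeatedly: locate the left-most unresolved segment, gather every
    remaining segment overlapping it on the reference, extract the longest
    (ties: smallest ref_start, forward strand, smallest query_start), then
    drop everything overlapping the extraction.
    """
    def overlaps(a: MatchSegment, b: MatchSegment) -> bool:
        return a.ref_start < b.ref_end and b.ref_start < a.ref_end

    remaining = list(segments)
    kept: list[MatchSegment] = []
    while remaining:
        opener = min(
            remaining,
            key=lambda s: (s.ref_start, s.ref_end,
                           s.strand is Strand.REVERSE, s.query_start),
        )
        conflict = [s for s in remaining if overlaps(s, opener)]
        winner = min(
            conflict,
            key=lambda s: (-s.length, s.ref_start,
                           s.strand is Strand.REVERSE, s.query_start),
        )
        kept.append(winner)
        remaining = [s for s in remaining if not overlaps(s, winner)]
    return sorted(kept, key=lambda s: s.ref_start)
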