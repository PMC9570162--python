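"""Similarity scoring and query rearrangement.

Each query's similarity to the reference is the fraction of its bases placed
by the optimal tiling, expressed as a percentage truncated (floored, never
rounded) to three decimals.  Multiple queries are ranked most-similar first;
that order drives both the stacked dot plot (bottom to top) and the
rearranged FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError, ParameterError, UsageError
from .kmer_align import MatchSegment
from .optimal import Tiling
from .seqio import SequenceRecord

__all__ = [
    "QueryResult",
    "similarity_percent",
    "rank_queries",
    "overall_similarity",
]


def similarity_percent(mapped: int, total: int) -> float:
    """``100 * mapped / total`` truncated to exactly three decimal places.

    Truncation is done in integer arithmetic (thousandths of a percent), so
    72,098/72,100 gives 99.997 while the pooled 576,855/576,874 gives 99.996
    even though its exact value 99.99671…% would *round* to 99.997.
    """
    if total <= 0:
        raise ParameterError(f"total must be positive, got {total}")
    if mapped < 0 or mapped > total:
        raise ConsistencyError(
            f"mapped ({mapped}) must lie in [0, total={total}]"
        )
    return (100_000 * mapped // total) / 1000


@dataclass(frozen=True)
class QueryResult:
    """Everything known about one query after the full pipeline."""

    query: SequenceRecord
    basic_segments: tuple[MatchSegment, ...]
    tiling: Tiling
    mapped_bases: int
    similarity: float

    def __post_init__(self) -> None:
        if self.mapped_bases != self.tiling.mapped_bases:
            raise ConsistencyError("mapped_bases disagrees with tiling")
        if self.similarity != similarity_percent(self.mapped_bases,
                                                 self.query.length):
            raise ConsistencyError("similarity disagrees with mapped_bases")


def make_query_result(
    query: SequenceRecord,
    basic_segments: list[MatchSegment],
    tiling: Tiling,
) -> QueryResult:
    """Assemble a consistent :class:`QueryResult` from pipeline pieces."""
    return QueryResult(
        query=query,
        basic_segments=tuple(basic_segments),
        tiling=tiling,
        mapped_bases=tiling.mapped_bases,
        similarity=similarity_percent(tiling.mapped_bases, query.length),
    )


def rank_queries(results: list[QueryResult]) -> list[QueryResult]:
    """Stable sort, most similar first; ties by mapped bases, then input order.

    The returned order is the bottom-to-top stacking order of the rearranged
    plot and the record order of the rearranged FASTA.
    """
    if not results:
        raise UsageError("rank_queries requires at least one result")
    return sorted(results, key=lambda r: (-r.similarity, -r.mapped_bases))


def overall_similarity(results: list[QueryResult]) -> float:
    """Pooled similarity: total mapped bases over total query bases."""
    if not results:
        raise UsageError("overall_similarity requires at least one result")
    return similarity_percent(
        sum(r.mapped_bases for r in results),
        sum(r.query.length for r in results),
    )
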