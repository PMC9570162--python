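"""End-to-end alignment pipeline: index, align, tile, score.

Thin orchestration over :mod:`kmer_align`, :mod:`optimal` and
:mod:`rearrange`; the CLI and the test fixtures both drive this entry point.
"""

from __future__ import annotations

import logging

from .errors import UsageError
from .kmer_align import DEFAULT_K, build_kmer_index, align_query
from .optimal import Tiling, tile_jointly
from .rearrange import QueryResult, make_query_result
from .seqio import SequenceRecord

__all__ = ["align_queries"]

log = logging.getLogger(__name__)


def align_queries(
    reference: SequenceRecord,
    queries: list[SequenceRecord],
    k: int = DEFAULT_K,
    threshold: int | None = None,
) -> list[QueryResult]:
    """Run basic alignment and joint optimal tiling for every query.

    Reference-axis conflicts are resolved across *all* queries together, so
    each reference region is explained by the single longest segment any
    query offers.  Results are returned in query input order; rank them with
    :func:`contigplot.rearrange.rank_queries` for the rearranged outputs.
    """
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        raise UsageError("duplicate query ids in input")
    index = build_kmer_index(reference, k)
    log.info("indexed %s: %d distinct %d-mers", reference.id,
             len(index.table), k)
    basic: dict[str, list] = {}
    pooled = []
    for query in queries:
        segs = align_query(index, query, threshold)
        basic[query.id] = segs
        pooled.extend(segs)
        log.info("aligned %s: %d segments", query.id, len(segs))
    tilings = tile_jointly(pooled)
    results = []
    for query in queries:
        tiling = tilings.get(query.id)
        if tiling is None:
            tiling = Tiling(query_id=query.id, segments=(), mapped_bases=0)
        results.append(make_query_result(query, basic[query.id], tiling))
    return results
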