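"""Text outputs: the optimal segment listing and the rearranged FASTA.

The optimal listing is FASTA-adjacent: one header per tiling segment,
``>query_id<TAB>initial_position<TAB>aligned_position`` with the
strand-normalized subsequence wrapped on the following lines.
``initial_position`` is the 1-based start on the original query,
``aligned_position`` the 1-based start on the reference.  Concatenating the
subsequences in file order reconstructs the reference-ordered assembly.

The rearranged FASTA carries the full original query sequences, most
similar first, with a ``similarity=`` annotation in each description.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError
from .optimal import assemble_optimal_sequence
from .rearrange import QueryResult
from .seqio import SequenceRecord, sanitize_sequence, write_fasta

__all__ = [
    "OptimalTextRecord",
    "write_optimal_text",
    "read_optimal_text",
    "write_rearranged_fasta",
]

_WRAP = 70


@dataclass(frozen=True)
class OptimalTextRecord:
    """One tiling segment as written to the optimal text listing."""

    query_id: str
    initial_position: int   # 1-based on the original query
    aligned_position: int   # 1-based on the reference
    subsequence: str

    def __post_init__(self) -> None:
        if not self.subsequence:
            raise FormatError("optimal text record with empty subsequence")
        if self.initial_position < 1 or self.aligned_position < 1:
            raise FormatError("positions in optimal text are 1-based (>= 1)")


def write_optimal_text(results: list[QueryResult], path: str | Path) -> None:
    """Write every tiling segment of every query, queries in input order."""
    with open(Path(path), "w", encoding="utf-8") as handle:
        for res in results:
            for ref_start, query_start, sub in assemble_optimal_sequence(
                res.tiling, res.query
            ):
                handle.write(f">{res.query.id}\t{query_start}\t{ref_start}\n")
                for i in range(0, len(sub), _WRAP):
                    handle.write(sub[i : i + _WRAP] + "\n")


def read_optimal_text(path: str | Path) -> list[OptimalTextRecord]:
    """Parse a file produced by :func:`write_optimal_text`."""
    records: list[OptimalTextRecord] = []
    header: tuple[str, int, int] | None = None
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        qid, init, aligned = header
        records.append(
            OptimalTextRecord(qid, init, aligned,
                              sanitize_sequence("".join(body)))
        )

    with open(Path(path), encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                if len(fields) != 3:
                    raise FormatError(
                        f"malformed optimal text header: {line!r}"
                    )
                header = (fields[0], int(fields[1]), int(fields[2]))
                body = []
            else:
                if header is None:
                    raise FormatError("sequence before first header")
                body.append(line)
        flush()
    return records


def write_rearranged_fasta(ranked: list[QueryResult], path: str | Path) -> None:
    """Write the full query sequences in ranked order (most similar first)."""
    records = [
        SequenceRecord(
            id=res.query.id,
            seq=res.query.seq,
            description=f"similarity={res.similarity:.3f}",
        )
        for res in ranked
    ]
    write_fasta(records, path)
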