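"""FASTA input/output and nucleotide string utilities.

Sequences are held as plain upper-case strings over the five-letter DNA
alphabet ``A C G T N``.  Everything downstream (k-mer indexing, exact-match
merging, plotting) assumes this canonical form, so all input passes through
:func:`sanitize_sequence` exactly once, at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import FormatError, UsageError

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "sanitize_sequence",
    "reverse_complement",
    "FASTA_EXTENSIONS",
]

#: Extensions accepted without a warning.
FASTA_EXTENSIONS = {".fasta", ".fa", ".fsa", ".fna"}

_ALPHABET = frozenset("ACGTN")

# IUPAC ambiguity codes collapse to N: the aligner does not consider
# uncertain bases, and an N never seeds or extends a match.
_SANITIZE = str.maketrans(
    {
        "U": "T",
        "R": "N", "Y": "N", "S": "N", "W": "N", "K": "N", "M": "N",
        "B": "N", "D": "N", "H": "N", "V": "N", "X": "N", "N": "N",
    }
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence.

    Attributes
    ----------
    id:
        First whitespace-delimited token of the FASTA header; never empty.
    seq:
        Upper-case sequence over ``{A, C, G, T, N}``.
    description:
        Remainder of the header after the id; may be empty.
    """

    id: str
    seq: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record must have a non-empty id")

    @property
    def length(self) -> int:
        return len(self.seq)


def sanitize_sequence(raw: str) -> str:
    """Canonicalize a raw sequence string.

    Upper-cases, strips whitespace, maps RNA ``U`` to ``T`` and every IUPAC
    ambiguity code to ``N``.  Alignment-gap dashes are removed with a warning.
    Any other character is a :class:`FormatError`.
    """
    s = "".join(raw.split()).upper()
    if "-" in s:
        warnings.warn("gap characters '-' stripped from sequence", stacklevel=2)
        s = s.replace("-", "")
    s = s.translate(_SANITIZE)
    bad = set(s) - _ALPHABET
    if bad:
        raise FormatError(
            f"invalid sequence characters: {', '.join(sorted(bad))!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(seq) - _ALPHABET
    if bad:
        raise FormatError(
            f"invalid sequence characters: {', '.join(sorted(bad))!r}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into sanitized records.

    Records keep file order; multi-line bodies are concatenated.  Raises
    :class:`FormatError` for files without a ``>`` header or with an empty
    record body, and the usual OSError family for missing files.
    """
    path = Path(path)
    if path.suffix.lower() not in FASTA_EXTENSIONS:
        warnings.warn(
            f"unusual FASTA extension {path.suffix!r} on {path.name}",
            stacklevel=2,
        )
    with open(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
        handle.seek(0)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = sanitize_sequence(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            parts = rec.description.split(maxsplit=1)
            desc = parts[1] if len(parts) > 1 else ""
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    line_width: int = 70,
) -> None:
    """Write records as FASTA with bodies wrapped at ``line_width`` columns.

    ``read_fasta(write_fasta(x)) == x`` for sanitized records.
    """
    records = list(records)
    if not records:
        raise UsageError("no records to write")
    if line_width < 1:
        raise UsageError(f"line_width must be >= 1, got {line_width}")
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, rec.length, line_width):
                handle.write(rec.seq[i : i + line_width] + "\n")
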