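"""Synthetic validation data: random references, splitting, shuffling.

The standard self-check for a contig plotter: take a reference, cut it into
fragments, shuffle their order, and ask the aligner to place every fragment
back — a clean run should recover essentially every base.  This module
generates that experiment deterministically from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UsageError
from .seqio import SequenceRecord

__all__ = [
    "SplitPlan",
    "random_sequence",
    "make_split_plan",
    "split_reference",
    "shuffle_fragments",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SplitPlan:
    """Where a reference is cut and how the pieces are to be shuffled."""

    n_fragments: int
    chunk_size: int | None
    boundaries: tuple[int, ...]  # internal 0-based cut positions
    seed: int


def random_sequence(
    length: int, seed: int, record_id: str | None = None
) -> SequenceRecord:
    """Uniform i.i.d. A/C/G/T sequence, deterministic for a given seed."""
    if length < 1:
        raise ParameterError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    if record_id is None:
        record_id = f"synthetic_{length}bp_seed{seed}"
    return SequenceRecord(id=record_id, seq=seq)


def make_split_plan(
    ref_length: int, n: int, chunk_size: int | None = None, seed: int = 0
) -> SplitPlan:
    """Cut positions for n fragments: n-1 chunks of ``chunk_size`` (default
    ``floor(length / n)``), remainder in the last fragment."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    size = chunk_size if chunk_size is not None else ref_length // n
    if n > 1 and (size < 1 or (n - 1) * size >= ref_length):
        raise ParameterError(
            f"chunk size {size} with {n} fragments does not fit a "
            f"{ref_length} bp reference"
        )
    boundaries = tuple(size * i for i in range(1, n))
    return SplitPlan(n_fragments=n, chunk_size=chunk_size,
                     boundaries=boundaries, seed=seed)


def split_reference(
    ref: SequenceRecord, n: int, chunk_size: int | None = None
) -> list[SequenceRecord]:
    """Partition the reference into n fragments ``<ref.id>_T0 … _T<n-1>``.

    The fragments concatenate back to the reference exactly; the last one
    carries the remainder.
    """
    plan = make_split_plan(ref.length, n, chunk_size)
    edges = (0, *plan.boundaries, ref.length)
    return [
        SequenceRecord(id=f"{ref.id}_T{i}", seq=ref.seq[edges[i]:edges[i + 1]])
        for i in range(n)
    ]


def shuffle_fragments(
    fragments: list[SequenceRecord], seed: int
) -> list[SequenceRecord]:
    """Seeded uniform permutation of the fragment list; records unchanged."""
    if not fragments:
        raise UsageError("cannot shuffle an empty fragment list")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fragments))
    return [fragments[i] for i in order]
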