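"""Exception hierarchy shared by all contigplot modules.

The CLI maps these onto exit codes: usage/parameter/format problems exit 2,
I/O failures exit 1 (see :mod:`contigplot.cli`).
"""


class ContigplotError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ContigplotError, ValueError):
    """Malformed input data (bad FASTA, invalid characters, empty records)."""


class ParameterError(ContigplotError, ValueError):
    """An argument outside its documented domain (k, threshold, lengths)."""


class UsageError(ContigplotError, ValueError):
    """An API contract violation (mixed query ids, empty input lists)."""


class ConsistencyError(ContigplotError, RuntimeError):
    """An internal invariant failed (segment out of bounds, mapped > total)."""
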