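"""Exception hierarchy.

All domain errors derive from :class:`MrnaLangError` so callers (and the
CLI) can distinguish validation failures from genuine I/O problems.
"""


class MrnaLangError(Exception):
    """Base class for all domain-level errors raised by this package."""


class AmbiguousBaseError(MrnaLangError):
    """Sequence contains a character outside {A,C,G,U,T} (any case).

    Ambiguity codes such as N are rejected rather than skipped: dropping
    bases would break codon framing and the statistics are defined on a
    strict 4-letter alphabet.
    """


class SegmentRangeError(MrnaLangError):
    """Requested amino-acid segment lies outside the coding sequence."""


class FramingError(MrnaLangError):
    """Sequence length is not a multiple of 3 (or too short to frame)."""


class JoinError(MrnaLangError):
    """FASTA ids and annotation-table ids do not correspond one-to-one."""

    def __init__(self, msg, fasta_only=(), table_only=()):
        super().__init__(msg)
        self.fasta_only = tuple(fasta_only)
        self.table_only = tuple(table_only)


class EmptySequenceError(MrnaLangError):
    """Statistic requested on an empty sequence."""


class SequenceTooShortError(MrnaLangError):
    """Sequence too short for the requested statistic (e.g. < 2 bases for D2)."""


class EmptyDatasetError(MrnaLangError):
    """Operation requires at least one record."""


class DegenerateInputError(MrnaLangError):
    """Correlation requested on a constant vector."""


class ShapeError(MrnaLangError):
    """Paired vectors have mismatched lengths."""


class ModelError(MrnaLangError):
    """Markov model violates its invariants (row sums, stationarity, signs)."""


class ConfigError(MrnaLangError):
    """Synthetic study configuration violates its invariants."""


class LabelError(MrnaLangError):
    """Class label not in the structural/kinetic vocabulary."""
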