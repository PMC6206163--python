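"""Exception hierarchy shared across the package."""


class EnhwalkError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(EnhwalkError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class IntervalBoundsError(EnhwalkError):
    """A genomic interval falls outside its chromosome, or the chromosome is absent."""


class SequenceRejectedError(EnhwalkError):
    """A sequence failed normalization policy (too ambiguous, too short, empty)."""

    def __init__(self, message: str, seq_id: str | None = None):
        self.seq_id = seq_id
        if seq_id is not None:
            message = f"sequence {seq_id!r}: {message}"
        super().__init__(message)


class EncodingError(EnhwalkError):
    """A non-ACGT character reached the walk encoder; carries the position."""


class DegenerateSeriesError(EnhwalkError):
    """A statistic is undefined on the given series (zero variance, too short...)."""


class SchemaError(EnhwalkError):
    """Feature names or column order do not match a model's registry."""
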