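"""Exception hierarchy for the trfbin pipeline."""


class TRFBinError(Exception):
    """Base class for all trfbin errors."""


class ParseError(TRFBinError):
    """A text input (tRNAscan table, GTF, sample sheet) could not be parsed."""


class InvalidRecordError(ParseError):
    """A record parsed but violates an invariant (e.g. begin == end)."""


class FormatError(TRFBinError):
    """An alignment or sequence file is unreadable or of a foreign format."""


class StructureError(TRFBinError):
    """A secondary-structure string does not resolve to a clover leaf."""


class ConsistencyError(TRFBinError):
    """Structure landmarks contradict the sequence (anticodon outside A-loop)."""


class ValidationError(TRFBinError):
    """Invalid configuration or arguments (bad groups, missing paths, ...)."""


class DegenerateSampleError(TRFBinError):
    """A sample shares no nonzero bins with the normalization reference."""


class PlanError(TRFBinError):
    """A simulation plan references a bin that was never constructed."""


class SizingError(TRFBinError):
    """The simulated genome cannot accommodate the requested placement."""
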