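"""Exception hierarchy for the clockevol pipeline."""


class ClockevolError(Exception):
    """Base class for all pipeline errors."""


class InputError(ClockevolError):
    """Missing/empty input or unusable file content."""


class AlignmentError(ClockevolError):
    """Sequences violate multiple-sequence-alignment invariants."""


class FrameError(AlignmentError):
    """Alignment length is not a multiple of the codon size."""


class DegenerateAlignmentError(AlignmentError):
    """A filter or operation left fewer sequences than an analysis needs."""


class TreeParseError(ClockevolError):
    """Malformed Newick input."""


class ConfigurationError(ClockevolError):
    """Invalid parameter combination passed to an operation."""


class NumericError(ClockevolError):
    """Non-finite quantity encountered during a likelihood computation."""
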