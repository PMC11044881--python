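"""Exception hierarchy for allelekde."""


class AlleleKDEError(Exception):
    """Base class for all allelekde errors."""


class FastaError(AlleleKDEError, ValueError):
    """Malformed or unusable sequence input."""


class AlignmentLengthError(FastaError):
    """Sequences in one alignment do not all share the same length."""


class GapError(FastaError):
    """A gap character was found; indels cannot be used with this method."""


class AlphabetError(FastaError):
    """A character outside {A, C, G, T} (e.g. an ambiguity code) was found."""


class EmptyAlignmentError(FastaError):
    """The input contains no sequence records."""


class CapacityError(AlleleKDEError):
    """A requested space would exceed its materialization guard."""


class ConfigurationError(AlleleKDEError, ValueError):
    """Mutually inconsistent objects were combined (space/spec/table)."""
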