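"""Exception hierarchy for hybridtrace."""


class HybridtraceError(Exception):
    """Base class for all package errors."""


class AlignmentError(HybridtraceError):
    """Records in an alignment have unequal lengths or duplicate ids."""


class AlphabetError(HybridtraceError):
    """A residue outside the permitted nucleotide/IUPAC/gap alphabet."""


class FormatError(HybridtraceError):
    """A malformed site-matrix table (bad header, ragged rows, bad positions)."""


class GroupingError(HybridtraceError):
    """A requested taxon group is absent or empty."""


class DataQualityError(HybridtraceError):
    """Input data violate a method precondition (e.g. IUPAC code in a parental row)."""


class InsufficientDataError(HybridtraceError):
    """Too few records/characters for the requested operation."""


class ShapeError(HybridtraceError):
    """Mismatched sequence/profile lengths."""


class CapacityError(HybridtraceError):
    """Problem size exceeds the configured exact-search cap."""


class UndefinedStatisticError(HybridtraceError):
    """A requested index is undefined for this input (e.g. CI on a zero-length tree)."""


class ConfigError(HybridtraceError):
    """Invalid simulation or run configuration."""
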