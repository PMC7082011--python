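"""Exception hierarchy shared across the package."""


class MitopopError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(MitopopError):
    """Ragged or otherwise malformed alignment."""


class AlphabetError(MitopopError):
    """Sequence contains a character outside {A, C, G, T, -, N}."""


class MetadataError(MitopopError):
    """Specimen/site bookkeeping problem (unknown specimen, bad table)."""


class CoordinateError(MitopopError):
    """Out-of-range alignment position or geographic coordinate."""


class InsufficientSampleError(MitopopError):
    """Statistic requested on a sample too small to define it."""


class UndefinedDistanceError(MitopopError):
    """Pairwise distance undefined (no overlapping called sites)."""


class AmbiguousPartitionError(MitopopError):
    """Network cannot be split into haplogroups by the requested cut rule."""
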