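"""Exception hierarchy for spatialprep."""


class SpatialPrepError(Exception):
    """Base class for all package errors."""


class ValidationError(SpatialPrepError):
    """A domain object violates one of its invariants."""


class FormatError(SpatialPrepError):
    """An input file does not follow any accepted dialect."""


class ConversionError(SpatialPrepError):
    """Inputs are individually well-formed but mutually inconsistent."""
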