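"""Exception hierarchy shared across the pipeline stages."""


class TracefateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TracefateError, ValueError):
    """A parameter is outside its documented range."""


class DegenerateInputError(TracefateError, ValueError):
    """Input is structurally valid but carries no usable information
    (all-zero intensities, zero denominator enrichment, ...)."""


class InvalidMeasurementError(TracefateError, ValueError):
    """A physical measurement violates its invariant (e.g. OCR <= 0)."""


class SchemaError(TracefateError, ValueError):
    """A table is missing required columns, conditions or replicates."""


class NoInformationError(TracefateError, ValueError):
    """A model fit was requested on data with no events/information."""


class DegenerateStratificationError(TracefateError, ValueError):
    """A median split was requested on a constant expression vector."""
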