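"""Exception hierarchy for the IMT measurement pipeline."""


class CimtError(Exception):
    """Base class for all package errors."""


class ValidationError(CimtError, ValueError):
    """An argument violates a documented precondition."""


class RoiFailure(CimtError, RuntimeError):
    """The region of interest around the intima-media complex could not be
    located reliably (too few template matches agree on a vertical position)."""


class InitializationFailure(CimtError, RuntimeError):
    """An initial boundary (lumen-intima or media-adventitia) could not be
    estimated, e.g. the whole region lies below the intensity threshold."""


class MeasurementError(CimtError, RuntimeError):
    """Agreement statistics are undefined for the given inputs
    (e.g. zero variance in a correlation)."""
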