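"""Exception hierarchy for phenocount."""


class PhenocountError(Exception):
    """Base class for all phenocount errors."""


class InvalidScalerError(PhenocountError):
    """Elevation scaler has zero or negative scale (degenerate site design)."""


class MissingSiteError(PhenocountError, KeyError):
    """A site id was requested that has no peak-abundance parameter."""


class InvalidParameterError(PhenocountError, ValueError):
    """A parameter set violates its domain constraints."""


class InsufficientDataError(PhenocountError):
    """The dataset cannot support the requested model structure."""


class SelectionError(PhenocountError):
    """Model selection was attempted on an empty set of converged fits."""


class MissingClimateError(PhenocountError):
    """A required climate window has missing monthly records."""
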