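"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid (non-positive extent, zero streets, ...)."""


class DomainError(ValueError):
    """An input violates a geometric or numeric precondition (point outside the
    city extent, mismatched raster dimensions, ...)."""


class MissingExposureError(ValueError):
    """A dwelling's buffer contains no street sampling points, so no exposure
    value can be computed.  Callers typically exclude the participant and log."""
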