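"""Exception types shared across the package."""


class VesselmarkError(Exception):
    """Base class for all package errors."""


class FormatError(VesselmarkError):
    """A file does not conform to the expected tabular format."""


class ValidationError(VesselmarkError):
    """Parsed content violates a domain constraint (unknown token, bad range...)."""
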