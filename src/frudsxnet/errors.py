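"""Exception types shared across the package."""


class FrudsxError(Exception):
    """Base class for package errors."""


class SchemaError(FrudsxError):
    """A required column is missing or unmappable."""


class IntegrityError(FrudsxError):
    """Table content violates an invariant (e.g. duplicate cell ids)."""


class ParseError(FrudsxError):
    """A field could not be parsed into its required type/range."""


class ConfigError(FrudsxError):
    """A configuration value is out of range or inconsistent."""


class SamplingError(FrudsxError):
    """Rejection sampling failed to accept within the attempt budget."""


class StateSpaceError(FrudsxError):
    """Exact enumeration requested on a problem too large to enumerate."""
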