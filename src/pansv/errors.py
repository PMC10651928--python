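"""Exception hierarchy."""


class PansvError(Exception):
    """Base class for all package errors."""


class ValidationError(PansvError):
    """Input violates a documented invariant."""


class FormatError(PansvError):
    """A file could not be parsed; the message names the offending record."""


class ConfigurationError(PansvError):
    """Inconsistent configuration (e.g. unknown caller identifier)."""
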