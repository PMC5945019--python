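"""Exception hierarchy for the sfcmpipe pipeline."""


class SfcmError(Exception):
    """Base class for all sfcmpipe errors."""


class FormatError(SfcmError):
    """A file does not have the expected layout (e.g. missing header)."""


class ParseError(SfcmError):
    """A cell in a table could not be parsed as the expected type."""


class IntegrityError(SfcmError):
    """Data violate an internal consistency requirement."""


class DomainError(SfcmError):
    """An operation was called on input outside its mathematical domain."""


class ConfigurationError(SfcmError):
    """A configuration value is invalid or inconsistent."""


class PipelineError(SfcmError):
    """A pipeline stage could not produce a usable result."""
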