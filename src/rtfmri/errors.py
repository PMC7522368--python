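"""Exception hierarchy shared across the toolkit."""


class RtfmriError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(RtfmriError):
    """A session or scanner configuration is missing or inconsistent."""


class FormatError(RtfmriError):
    """A scanner file could not be interpreted in the configured dialect."""


class ProtocolError(RtfmriError):
    """A streamed message violates the header/payload contract."""


class AnalysisError(RtfmriError):
    """An analysis was asked to operate on invalid inputs (e.g. empty mask)."""
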