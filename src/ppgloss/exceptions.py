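"""Exception hierarchy for ppgloss."""


class PPGLossError(Exception):
    """Base class for all ppgloss errors."""


class ConfigError(PPGLossError, ValueError):
    """A configuration object violates one of its invariants."""


class FormatError(PPGLossError, ValueError):
    """An on-disk record or table does not conform to the expected layout."""


class RecordError(PPGLossError, ValueError):
    """A PPG record is unsuitable for the requested analysis."""
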