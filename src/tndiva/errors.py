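"""Exception hierarchy for tndiva."""


class TnDivAError(Exception):
    """Base class for all tndiva errors."""


class ParseError(TnDivAError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(TnDivAError):
    """Input violated a structural invariant (coordinates, counts, duplicates)."""


class ConfigurationError(TnDivAError):
    """Parameters are inconsistent or outside their allowed range."""
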