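"""Exception hierarchy shared across the package."""


class AquasigError(Exception):
    """Base class for all package errors."""


class ParseError(AquasigError):
    """A sequence or alignment file could not be parsed."""


class ValidationError(AquasigError):
    """A loaded configuration or data structure violates its invariants."""


class AnalysisError(AquasigError):
    """An analysis step cannot proceed on the given input."""
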