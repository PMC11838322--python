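"""Exception hierarchy for pfaslevels."""


class PfasLevelsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PfasLevelsError):
    """Invalid or incomplete tolerance/bounds configuration."""


class DomainError(PfasLevelsError, ValueError):
    """Operation called with values outside its scientific domain."""


class FormatError(PfasLevelsError):
    """Malformed input file (missing columns, bad spectrum block...)."""


class InsufficientDataError(PfasLevelsError):
    """Not enough observations for the requested computation."""
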