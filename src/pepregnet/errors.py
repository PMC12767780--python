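"""Exception hierarchy shared across the package."""


class PepregnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PepregnetError):
    """Input data violates a structural invariant (negative counts, bad IDs, ...)."""


class FormatError(PepregnetError):
    """A file does not parse as the format it claims to be."""


class InvalidConfigError(PepregnetError):
    """A simulation or analysis configuration is internally inconsistent."""


class UndefinedStatisticError(PepregnetError):
    """A requested statistic is undefined for the given input (e.g. zero variance)."""
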