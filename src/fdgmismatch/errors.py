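"""Exception hierarchy shared across the package."""


class FdgMismatchError(Exception):
    """Base class for package errors."""


class ValidationError(FdgMismatchError, ValueError):
    """Input violates a documented contract (out-of-range value, bad shape...)."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but degenerate (e.g. all-zero uptake vector)."""


class ConfigError(FdgMismatchError, ValueError):
    """Simulation or pipeline configuration is inconsistent or incomplete."""


class InsufficientDataError(FdgMismatchError, ValueError):
    """Too few observations for the requested statistic."""
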