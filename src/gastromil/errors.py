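"""Exception hierarchy shared across the pipeline."""


class GastromilError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GastromilError, ValueError):
    """Caller supplied data that violates a precondition."""


class UnsupportedMagnificationError(InvalidInputError):
    """Requested magnification exceeds the slide's base magnification."""


class DegenerateStainError(GastromilError):
    """No usable optical-density signal to estimate a stain basis from."""


class ContractViolationError(GastromilError):
    """Two pipeline stages disagree on shapes or alignment."""


class EmptyBagError(InvalidInputError):
    """A feature bag with zero instances where at least one is required."""


class FormatError(GastromilError):
    """On-disk artifact is unreadable or has an incompatible schema."""


class DependencyError(GastromilError):
    """A required upstream artifact is missing; names the stage to run."""
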