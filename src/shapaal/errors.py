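"""Exception hierarchy shared across the package."""


class ShapaalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ShapaalError):
    """A data file violates the expected record layout."""


class ParseError(FormatError):
    """A field in a data file is not numeric."""


class EmptyInputError(ShapaalError):
    """An operation received an empty dataset or vector."""


class ContractError(ShapaalError):
    """A caller violated a documented precondition."""


class DegenerateScaleError(ShapaalError):
    """Normalization was requested for (near-)constant data."""


class ConfigError(ShapaalError):
    """A configuration value is invalid or inconsistent."""


class FeasibilityError(ShapaalError):
    """An exact computation was requested above its enumeration cap."""


class TrainingDivergenceError(ShapaalError):
    """Optimization produced a non-finite loss.

    Carries the epoch index at which the divergence was detected.
    """

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch
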