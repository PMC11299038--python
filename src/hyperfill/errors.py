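"""Exception hierarchy shared across the package."""


class HyperfillError(Exception):
    """Base class for all package errors."""


class FormatError(HyperfillError):
    """A model file could not be parsed under the named standard."""


class EmptyModelError(HyperfillError):
    """A parsed model contains no reactions."""


class IntegrityError(HyperfillError):
    """A reference inside a model or ranking cannot be resolved."""


class DimensionError(HyperfillError):
    """Array shapes do not satisfy an operation's contract."""


class ContractError(HyperfillError):
    """A precondition of an operation was violated."""


class ConfigError(HyperfillError):
    """An invalid configuration value."""


class SamplingError(HyperfillError):
    """Negative/decoy resampling exhausted its retry budget."""


class TrainingError(HyperfillError):
    """Training produced a non-finite loss."""


class ExperimentError(HyperfillError):
    """An experiment harness received insufficient data."""
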