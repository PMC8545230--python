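"""Exception types shared across the package."""


class AssoaError(Exception):
    """Base class for package errors."""


class ConfigurationError(AssoaError, ValueError):
    """Invalid parameter, search space, or run configuration."""


class UnknownAlgorithmError(AssoaError, KeyError):
    """Requested optimizer identifier is not registered."""


class EvaluationError(AssoaError, ValueError):
    """Objective returned a non-finite value, or stale fitness was read."""


class StaleFitnessError(EvaluationError):
    """Fitness values were consumed before :func:`evaluate_population`."""
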