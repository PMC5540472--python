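"""Exception hierarchy for caresig."""


class CaresigError(Exception):
    """Base class for all caresig errors."""


class InputError(CaresigError, ValueError):
    """Invalid data passed to an operation (wrong shape, too short, ...)."""


class ConfigurationError(CaresigError, ValueError):
    """Invalid configuration (unknown joint, bad class counts, ...)."""


class SamplingError(CaresigError, ValueError):
    """Sampling rate too low to resolve the requested frequency content."""


class TrainingError(CaresigError, RuntimeError):
    """Optimisation failed (diverged to NaN, ...)."""


class NotFittedError(CaresigError, RuntimeError):
    """A model or scaler was used before being fitted."""
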