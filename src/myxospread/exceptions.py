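"""Exception types shared across the package."""


class MyxospreadError(Exception):
    """Base class for package errors."""


class ConfigurationError(MyxospreadError):
    """Invalid or inconsistent configuration / parameters."""


class NumericalError(MyxospreadError):
    """Solver produced non-finite or out-of-tolerance values."""


class InputError(MyxospreadError):
    """Invalid input data (too few points, malformed file, ...)."""
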