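"""Exception hierarchy used across the package."""


class LvcSpinError(Exception):
    """Base class for package errors."""


class InputError(LvcSpinError, ValueError):
    """Invalid argument values or incompatible shapes."""


class FormatError(LvcSpinError, ValueError):
    """Malformed on-disk data (trajectory or parametrization files)."""


class ConfigurationError(LvcSpinError, ValueError):
    """Missing or inconsistent run configuration."""


class NumericError(LvcSpinError, ArithmeticError):
    """Non-finite or otherwise pathological numerical result."""


class ConvergenceError(LvcSpinError, ArithmeticError):
    """An iterative scheme exceeded its safety bound."""
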