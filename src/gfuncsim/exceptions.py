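"""Exception hierarchy shared across the package."""


class GFuncError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(GFuncError, ValueError):
    """A model parameter is outside its admissible domain."""


class StructuralError(GFuncError, ValueError):
    """Mismatched vector shapes / malformed community structure."""


class CapabilityError(GFuncError, RuntimeError):
    """A requested capability (e.g. an analytic gradient) is unavailable."""


class NumericalDomainError(GFuncError, ArithmeticError):
    """A non-finite value was produced during evaluation or integration."""


class ConfigError(GFuncError, ValueError):
    """Invalid scenario configuration (schema violation, unknown key...)."""
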