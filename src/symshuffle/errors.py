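"""Exception hierarchy for symshuffle."""


class SymshuffleError(Exception):
    """Base class for all package errors."""


class ConfigError(SymshuffleError, ValueError):
    """A configuration file or scenario specification is invalid."""


class ParameterError(SymshuffleError, ValueError):
    """A model parameter violates its domain (e.g. non-positive width)."""


class NumericalError(SymshuffleError, RuntimeError):
    """A non-finite intermediate appeared during iteration."""
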