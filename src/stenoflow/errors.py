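"""Exception hierarchy for stenoflow."""


class StenoflowError(Exception):
    """Base class for all package-specific errors."""


class DomainError(StenoflowError, ValueError):
    """A physical parameter is outside its admissible range."""


class ResolutionError(StenoflowError, ValueError):
    """The lattice cannot resolve the requested feature."""


class GeometryError(StenoflowError, ValueError):
    """A geometric request is inconsistent (gap outside occluder, plane in solid, ...)."""


class StabilityError(StenoflowError, RuntimeError):
    """A solver setting violates the stability map (relaxation time, Mach number)."""


class DivergenceError(StenoflowError, RuntimeError):
    """The solution produced non-finite values; carries the first offending location."""


class ConfigError(StenoflowError, ValueError):
    """A run configuration is invalid (unknown preset, schema violation)."""
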