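"""Exception types shared across the package."""


class NanoQstrError(Exception):
    """Base class for package errors."""


class CifParseError(NanoQstrError):
    """A CIF document is missing a required tag or cannot be tokenised."""


class ValidationError(NanoQstrError):
    """An input violates a documented precondition."""


class EmptyParticleError(NanoQstrError):
    """Sphere carving produced a particle with no atoms."""


class MissingRegionError(NanoQstrError):
    """A region-restricted descriptor was requested for an empty region."""


class ConfigurationError(NanoQstrError):
    """A registry, parameter table or config is inconsistent."""
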