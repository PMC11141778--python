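"""Exception hierarchy for lymphflow."""


class LymphflowError(Exception):
    """Base class for all lymphflow errors."""


class ConfigurationError(LymphflowError):
    """A parameter or configuration value is invalid."""


class InvalidStateError(LymphflowError):
    """A simulation state violates a required invariant."""


class NumericalBlowupError(LymphflowError):
    """The solution left the stable low-Mach regime (NaN, rho<=0, |u| too large)."""


class GeometryError(LymphflowError):
    """A Lagrangian structure left the domain or overlaps a solid region."""
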