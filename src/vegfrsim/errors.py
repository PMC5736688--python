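"""Exception hierarchy for vegfrsim."""


class VegfrsimError(Exception):
    """Base class for all package errors."""


class ParameterValidationError(VegfrsimError, ValueError):
    """A parameter record violates a model invariant."""


class ParameterParseError(VegfrsimError, ValueError):
    """A parameter file could not be parsed."""


class UnknownEntityError(VegfrsimError, KeyError):
    """A named receptor, adapter, site, or species does not exist."""


class ConfigurationError(VegfrsimError, ValueError):
    """A run configuration is inconsistent (missing weights, bad variant, ...)."""


class SimulationError(VegfrsimError, RuntimeError):
    """The ODE solver failed to produce a solution."""


class ConservationError(VegfrsimError, RuntimeError):
    """A moiety conservation law was violated beyond tolerance."""
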