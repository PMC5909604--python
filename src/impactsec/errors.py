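"""Exception hierarchy for the impactsec model."""


class ImpactSecError(Exception):
    """Base class for all model errors."""


class InputValidationError(ImpactSecError):
    """An input table violates its schema or a domain constraint."""


class ConfigurationError(ImpactSecError):
    """A configuration value is missing, unknown, or inconsistent."""


class GenerationError(ImpactSecError):
    """A synthetic scenario configuration is infeasible."""


class MonteCarloError(ImpactSecError):
    """A Monte Carlo run failed; carries the draw index and cause."""
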