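"""Exception hierarchy shared across the pipeline."""


class CytonetError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CytonetError, ValueError):
    """Invalid simulation or run configuration."""


class ValidationError(CytonetError, ValueError):
    """Input table violates the cohort data contract."""


class DomainError(CytonetError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientData(CytonetError, ValueError):
    """Too few observations for the requested statistic."""


class FitError(CytonetError, RuntimeError):
    """A model fit is degenerate or refused (no events, no variation...)."""
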