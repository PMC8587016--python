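"""Exception hierarchy shared across the package."""


class PfasRiskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PfasRiskError):
    """A table or file does not match the expected schema."""


class ValidationError(PfasRiskError):
    """A record violates a domain invariant (e.g. non-positive concentration)."""


class UnitError(PfasRiskError):
    """An unknown or unsupported unit string."""


class FitError(PfasRiskError):
    """A model fit cannot proceed (too few points, degenerate data)."""


class DomainError(PfasRiskError):
    """An argument outside a function's mathematical domain."""


class ConfigError(PfasRiskError):
    """An invalid pipeline or simulation configuration."""


class PipelineError(PfasRiskError):
    """A stage of the end-to-end pipeline failed; message names the stage."""
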