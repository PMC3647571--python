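"""Exception hierarchy for ndrpath."""


class NdrPathError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NdrPathError):
    """A coefficient/profile/panel file does not conform to its schema."""


class CoefficientValidationError(NdrPathError):
    """A coefficient set violates a model invariant (e.g. lag outside (0,1))."""


class DomainError(NdrPathError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ContractError(NdrPathError):
    """A caller violated an operation precondition (e.g. missing covariate)."""


class PanelError(NdrPathError):
    """A longitudinal panel violates its invariants (duplicate keys, bad durations)."""


class EstimationError(NdrPathError):
    """Estimation cannot proceed (under-identification, insufficient periods)."""


class InstrumentSingularityError(EstimationError):
    """The GMM weighting matrix is singular; instruments are collinear."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class DiagnosticUnavailableError(NdrPathError):
    """A post-estimation test is undefined for this fit (df=0, zero variance...)."""
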