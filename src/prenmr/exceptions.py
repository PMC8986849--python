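"""Exception hierarchy for the analysis pipeline."""


class AnalysisError(ValueError):
    """Base class for all pipeline errors."""


class MismatchedConditionsError(AnalysisError):
    """Paired records do not share temperature/field/concentration metadata."""


class DegenerateDataError(AnalysisError):
    """Input data cannot support the requested fit (flat series, too few points...)."""


class UnidentifiableFitError(AnalysisError):
    """The model parameters are not constrained by the data (e.g. no curvature)."""


class RegimeGateError(AnalysisError):
    """Exchange kinetics requested without a tau_M-dominated diagnostics verdict."""


class InconsistentRatesError(AnalysisError):
    """Rate arithmetic produced a physically impossible value beyond noise."""
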