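"""Exception hierarchy for trialadapt."""


class TrialAdaptError(Exception):
    """Base class for all trialadapt errors."""


class ConfigurationError(TrialAdaptError, ValueError):
    """Invalid trial or experiment configuration."""


class DomainError(TrialAdaptError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DegenerateDataError(TrialAdaptError, ValueError):
    """Data degenerate for the requested computation (e.g. zero variance)."""


class EligibilityError(TrialAdaptError, ValueError):
    """A sub-group sample is too small for the requested computation."""


class AnalysisError(TrialAdaptError, RuntimeError):
    """Final outcome analysis impossible (no eligible matched pair)."""


class AdaptationExhaustedError(TrialAdaptError, RuntimeError):
    """No eligible sub-group remains to remove participants from."""
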