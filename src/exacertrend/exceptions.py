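"""Exception hierarchy for the pipeline."""


class ExacertrendError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExacertrendError):
    """Invalid configuration (bad probabilities, empty codelists, bad spans)."""


class EmptyDenominatorError(ExacertrendError):
    """A week's active-patient denominator is zero."""


class EmptyCohortError(ExacertrendError):
    """The analysis cohort is empty (no patient had an episode)."""
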