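"""Exception hierarchy for the worklife package."""


class WorkLifeError(Exception):
    """Base class for all errors raised by worklife."""


class ConfigurationError(WorkLifeError):
    """A configuration object or file is invalid; the message names the field."""


class DataError(WorkLifeError):
    """Input data violate a structural requirement (ordering, range, labels)."""


class EmptyGroupError(WorkLifeError):
    """A selection (stratum, group filter, origin state) contains no records."""


class FitError(WorkLifeError):
    """Model estimation failed (non-convergence, rank deficiency)."""


class MatchingError(WorkLifeError):
    """Mortality matching cannot attain the target death probability."""
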