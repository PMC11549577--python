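"""Exception hierarchy for the cost-effectiveness model."""


class MedceaError(Exception):
    """Base class for all package errors."""


class ConfigError(MedceaError, ValueError):
    """A scenario configuration failed to parse or validate."""


class DomainError(MedceaError, ValueError):
    """An operation was called outside its mathematical domain."""


class NoTimingDataError(DomainError):
    """Preparation-time summaries are required but absent.

    Distinct from a zero time difference: zero means the arms tied, this
    means the trial never recorded timing.
    """
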