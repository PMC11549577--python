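"""Per-administration effect estimates from trial arm outcomes.

A medication error is an administered dose deviating from the correct
weight-based dose by more than +/-10% in either direction (strictly:
``|deviation| > 0.10``). Each arm contributes its administration count, its
overdose and underdose counts, and a preparation-time summary; this module
turns a control/app arm pair into error rates, preventable errors per
administration, and mean time saved.

Counts are stored as floats because probabilistic sensitivity draws vary
them continuously around the observed integers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from .errors import DomainError, NoTimingDataError

Policy = Literal["pooled_denominator", "arm_rates"]

#: Tolerance for count-consistency checks on continuously-varied counts.
_TOL = 1e-9


@dataclass(frozen=True)
class TrialArmOutcome:
    """Observed (or sampled) outcomes for one trial arm."""

    n_administrations: float
    n_overdose: float
    n_underdose: float
    prep_time_mean_s: Optional[float] = None
    prep_time_sd_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_administrations <= 0:
            raise DomainError("arm must have a positive number of administrations")
        if self.n_overdose < 0 or self.n_underdose < 0:
            raise DomainError("error counts must be non-negative")
        if self.n_overdose + self.n_underdose > self.n_administrations + _TOL:
            raise DomainError("overdoses + underdoses exceed administrations")
        if self.prep_time_sd_s is not None and self.prep_time_sd_s < 0:
            raise DomainError("prep_time_sd_s must be non-negative")

    @property
    def errors(self) -> float:
        """Total errors: at most one (overdose or underdose) per administration."""
        return self.n_overdose + self.n_underdose

    @property
    def rate(self) -> float:
        return error_rate(self.errors, self.n_administrations)

    @property
    def has_timing(self) -> bool:
        return self.prep_time_mean_s is not None


@dataclass(frozen=True)
class EffectEstimate:
    """App-vs-control effect per administration."""

    err_per_admin: float
    error_rate_control: float
    error_rate_app: float
    time_saved_s: Optional[float] = None
    policy: Policy = "pooled_denominator"


def error_rate(n_errors: float, n_administrations: float) -> float:
    """Fraction of administrations with a dosing error."""
    if n_administrations <= 0:
        raise DomainError("error rate undefined for zero administrations")
    if n_errors < 0 or n_errors > n_administrations + _TOL:
        raise DomainError(f"error count {n_errors} outside [0, {n_administrations}]")
    return n_errors / n_administrations


def preventable_errors_per_admin(
    control: TrialArmOutcome,
    app: TrialArmOutcome,
    policy: Policy = "pooled_denominator",
) -> float:
    """Errors the app prevents per administration.

    ``pooled_denominator`` (default) divides the raw reduction in error
    counts by the control arm's administration count:
    ``((OD_c + UD_c) - (OD_a + UD_a)) / n_c``. ``arm_rates`` differences the
    two arm-specific rates instead. The two agree exactly when the arms are
    the same size. The result may be negative when the app arm performed
    worse; callers decide how to flag that.
    """
    if policy == "pooled_denominator":
        return (control.errors - app.errors) / control.n_administrations
    if policy == "arm_rates":
        return control.rate - app.rate
    raise DomainError(f"unknown policy {policy!r}")


def mean_time_saved(control: TrialArmOutcome, app: TrialArmOutcome) -> float:
    """Mean preparation time saved per administration, in seconds.

    Negative when the app is slower; the sign is preserved. Raises
    :class:`NoTimingDataError` when either arm lacks timing, which is a
    different statement than a measured zero difference.
    """
    if not control.has_timing or not app.has_timing:
        raise NoTimingDataError("preparation-time summaries missing for at least one arm")
    return control.prep_time_mean_s - app.prep_time_mean_s


def estimate_effect(
    control: TrialArmOutcome,
    app: TrialArmOutcome,
    policy: Policy = "pooled_denominator",
) -> EffectEstimate:
    """Bundle the per-administration effect estimates for a scenario.

    Time saved is ``None`` (not zero) when timing was never recorded.
    """
    time_saved: Optional[float]
    try:
        time_saved = mean_time_saved(control, app)
    except NoTimingDataError:
        time_saved = None
    return EffectEstimate(
        err_per_admin=preventable_errors_per_admin(control, app, policy),
        error_rate_control=control.rate,
        error_rate_app=app.rate,
        time_saved_s=time_saved,
        policy=policy,
    )
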