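"""ADE cascade: from preventable errors to expected harm and avoided cost.

The decision model converts preventable errors per administration into
expected adverse drug events (ADEs) and splits them into two NCC MERP
severity categories:

* Category E — temporary harm requiring intervention,
* Category F — temporary harm requiring initial or prolonged hospitalization.

The cascade is expected-value arithmetic (continuous expected counts, no
integer event simulation): N_ade = N_err * P(ADE), then
N_catE = N_ade * P(CatE) and N_catF = N_ade * P(CatF), with
P(CatE) = 1 - P(CatF) enforced structurally. An error causes at most one
ADE, and ADE-attributable mortality is excluded — both are structural
assumptions of the model, not parameters.

Costing
-------
Category F events cost the conditional length of stay (extra inpatient
days given an ADE) priced at the daily inpatient cost. Category E events
cost the excess reimbursement attached to complication-related stays; the
``cat_e_cost_formulation`` switch selects between

* ``excess_only`` — the excess amount alone (the literal reading of the
  published complication-cost figure), and
* ``stay_plus_excess`` — the implied base stay (excess / excess_fraction)
  plus the excess.

All monetary values are USD at the 2019 price level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DomainError

CatEFormulation = Literal["excess_only", "stay_plus_excess"]


@dataclass(frozen=True)
class AdeModel:
    """Probabilities and unit costs of the ADE cascade."""

    p_ade: float
    p_cat_f: float
    clos_days: float
    daily_cost: float
    excess_complication_cost: float
    excess_fraction: float = 0.9184
    cat_e_cost_formulation: CatEFormulation = "excess_only"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ade <= 1.0:
            raise DomainError(f"p_ade must lie in [0, 1], got {self.p_ade}")
        if not 0.0 <= self.p_cat_f <= 1.0:
            raise DomainError(f"p_cat_f must lie in [0, 1], got {self.p_cat_f}")
        if self.clos_days < 0:
            raise DomainError("conditional length of stay must be non-negative")
        if self.daily_cost < 0 or self.excess_complication_cost < 0:
            raise DomainError("costs must be non-negative")

    @property
    def p_cat_e(self) -> float:
        """Complement of P(Cat F); the two categories always sum to one."""
        return 1.0 - self.p_cat_f


@dataclass(frozen=True)
class AdeCascade:
    """Expected ADE counts per administration and their monetized value."""

    n_ade: float
    n_cat_e: float
    n_cat_f: float
    expected_cost_per_ade: float
    avoided_cost: float


def ade_per_admin(err_per_admin: float, p_ade: float) -> float:
    """Expected ADEs prevented per administration: N_err * P(ADE)."""
    return err_per_admin * p_ade


def split_categories(n_ade: float, p_cat_e: float) -> tuple[float, float]:
    """Split expected ADEs into (Cat E, Cat F); components sum to n_ade."""
    if not 0.0 <= p_cat_e <= 1.0:
        raise DomainError(f"p_cat_e must lie in [0, 1], got {p_cat_e}")
    n_cat_e = n_ade * p_cat_e
    return n_cat_e, n_ade - n_cat_e


def cost_cat_f(clos_days: float, daily_cost: float) -> float:
    """Cost of one Category F event: extra inpatient days x daily cost."""
    if clos_days < 0 or daily_cost < 0:
        raise DomainError("cost_cat_f requires non-negative inputs")
    return clos_days * daily_cost


def cost_cat_e(
    excess_complication_cost: float,
    excess_fraction: float,
    formulation: CatEFormulation = "excess_only",
) -> float:
    """Cost of one Category E event under the selected formulation.

    ``excess_only`` prices the event at the excess complication amount
    itself; ``stay_plus_excess`` adds the implied base stay
    (``excess / excess_fraction``).
    """
    if excess_complication_cost < 0:
        raise DomainError("excess complication cost must be non-negative")
    if formulation == "excess_only":
        return excess_complication_cost
    if formulation == "stay_plus_excess":
        if excess_fraction <= 0:
            raise DomainError("stay_plus_excess requires a positive excess fraction")
        return excess_complication_cost / excess_fraction + excess_complication_cost
    raise DomainError(f"unknown Cat E cost formulation {formulation!r}")


def expected_cost_per_ade(model: AdeModel) -> float:
    """Severity-weighted expected cost of one ADE."""
    ce = cost_cat_e(
        model.excess_complication_cost, model.excess_fraction, model.cat_e_cost_formulation
    )
    cf = cost_cat_f(model.clos_days, model.daily_cost)
    return model.p_cat_e * ce + model.p_cat_f * cf


def cascade(err_per_admin: float, model: AdeModel) -> AdeCascade:
    """Run the full per-administration cascade.

    ``err_per_admin`` may be negative for a probabilistic draw in which the
    app arm performed worse; the cascade then carries negative expected
    counts and a negative avoided cost through to the ROI stage, where such
    draws are flagged as never profitable.
    """
    n_ade = ade_per_admin(err_per_admin, model.p_ade)
    n_cat_e, n_cat_f = split_categories(n_ade, model.p_cat_e)
    unit_cost = expected_cost_per_ade(model)
    return AdeCascade(
        n_ade=n_ade,
        n_cat_e=n_cat_e,
        n_cat_f=n_cat_f,
        expected_cost_per_ade=unit_cost,
        avoided_cost=n_ade * unit_cost,
    )
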