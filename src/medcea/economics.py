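"""Program costs, incremental cost-effectiveness ratios, ROI and break-even.

The comparator (conventional drug preparation) carries no incremental
program cost, so the ICER numerator is the app's annual cost alone,
optionally net of the monetized time saved per administration. Annual
errors prevented are ``annual_administrations * err_per_admin``
(stationarity across the year). The upfront development cost is reference
information only and never enters any ratio.

All monetary values are USD at the 2019 price level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import DomainError


@dataclass(frozen=True)
class ProgramCosts:
    """Annual app-side costs: maintenance/update, training, optional device."""

    maintenance_annual: float
    training: tuple[tuple[str, float], ...] = ()
    device_annual: float = 0.0
    development_cost: Optional[float] = None  # reference only, excluded from ratios

    def __post_init__(self) -> None:
        if self.maintenance_annual < 0 or self.device_annual < 0:
            raise DomainError("program costs must be non-negative")
        for label, cost in self.training:
            if cost < 0:
                raise DomainError(f"training cost for {label!r} must be non-negative")

    @property
    def training_total(self) -> float:
        return sum(cost for _, cost in self.training)


@dataclass(frozen=True)
class CostEffectiveness:
    """Cost per prevented error and per prevented ADE at an annual volume."""

    cost_per_error: float
    cost_per_ade: float
    annual_cost: float
    annual_errors_prevented: float
    annual_ades_prevented: float


@dataclass(frozen=True)
class RoiResult:
    """Break-even administration count and ROI at a given volume.

    ``breakeven_real`` is the exact (fractional) count at which cumulative
    benefit equals the annual cost; ``breakeven_int`` the smallest integer
    volume achieving ROI >= 1. When the benefit per administration is not
    positive the program can never break even: ``never_profitable`` is set,
    ``breakeven_real`` is ``inf`` and ``breakeven_int`` is ``None`` — a
    signal, not an exception.
    """

    breakeven_real: float
    breakeven_int: Optional[int]
    benefit_per_admin: float
    annual_cost: float
    never_profitable: bool = False


def derive_maintenance(development_cost: float, fraction: float = 0.2) -> float:
    """Annual maintenance/update cost as a fraction of the development cost."""
    if development_cost < 0 or fraction < 0:
        raise DomainError("derive_maintenance requires non-negative inputs")
    return fraction * development_cost


def annual_program_cost(costs: ProgramCosts) -> float:
    """Total annual cost of running the app; development cost excluded."""
    return costs.maintenance_annual + costs.training_total + costs.device_annual


def icer_per_error(
    annual_cost: float,
    annual_administrations: float,
    err_per_admin: float,
    time_value_offset: float = 0.0,
) -> float:
    """Incremental cost per error prevented.

    ``time_value_offset`` is a monetary credit per administration (the
    valued time saved); it defaults to zero, which reproduces the published
    cost-effectiveness table.
    """
    if annual_administrations <= 0:
        raise DomainError("cost per error requires a positive administration volume")
    if err_per_admin <= 0:
        raise DomainError(
            "cost per error undefined when no errors are prevented "
            "(err_per_admin <= 0); check the trial arm counts"
        )
    return (annual_cost - annual_administrations * time_value_offset) / (
        annual_administrations * err_per_admin
    )


def icer_per_ade(cost_per_error: float, p_ade: float) -> float:
    """Incremental cost per ADE prevented: cost per error / P(ADE)."""
    if not 0.0 < p_ade <= 1.0:
        raise DomainError(f"p_ade must lie in (0, 1], got {p_ade}")
    return cost_per_error / p_ade


def benefit_per_admin(
    err_per_admin: float,
    p_ade: float,
    expected_cost_per_ade: float,
    time_saved_s: float = 0.0,
    wage_per_second: float = 0.0,
) -> float:
    """Monetary benefit of one app-assisted administration.

    Avoided-ADE value plus the valued preparation time saved. Negative time
    saved (app slower) is allowed and reduces the benefit.
    """
    if p_ade < 0 or expected_cost_per_ade < 0 or wage_per_second < 0:
        raise DomainError("probabilities, costs and wages must be non-negative")
    return err_per_admin * p_ade * expected_cost_per_ade + time_saved_s * wage_per_second


def breakeven_administrations(annual_cost: float, benefit: float) -> RoiResult:
    """Administrations needed for the benefit to cover the annual cost."""
    if annual_cost < 0:
        raise DomainError("annual cost must be non-negative")
    if benefit <= 0:
        return RoiResult(
            breakeven_real=math.inf,
            breakeven_int=None,
            benefit_per_admin=benefit,
            annual_cost=annual_cost,
            never_profitable=True,
        )
    real = annual_cost / benefit
    # smallest integer n with n * benefit >= annual_cost, robust to the
    # division having landed exactly on an integer
    n = max(0, math.floor(real))
    while n * benefit < annual_cost:
        n += 1
    return RoiResult(
        breakeven_real=real,
        breakeven_int=n,
        benefit_per_admin=benefit,
        annual_cost=annual_cost,
    )


def roi_at_volume(annual_cost: float, benefit: float, n_administrations: float) -> float:
    """Return on investment at a given annual volume: n * benefit / cost."""
    if annual_cost <= 0:
        raise DomainError("ROI requires a positive annual cost")
    if n_administrations < 0:
        raise DomainError("administration volume must be non-negative")
    return n_administrations * benefit / annual_cost


def cost_effectiveness(
    annual_cost: float,
    annual_administrations: float,
    err_per_admin: float,
    p_ade: float,
    time_value_offset: float = 0.0,
) -> CostEffectiveness:
    """Assemble the cost-effectiveness surface at an annual volume."""
    cpe = icer_per_error(annual_cost, annual_administrations, err_per_admin, time_value_offset)
    return CostEffectiveness(
        cost_per_error=cpe,
        cost_per_ade=icer_per_ade(cpe, p_ade),
        annual_cost=annual_cost,
        annual_errors_prevented=annual_administrations * err_per_admin,
        annual_ades_prevented=annual_administrations * err_per_admin * p_ade,
    )
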