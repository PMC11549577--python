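"""Deterministic evaluation of a scenario: trial effect -> cascade -> economics.

This module binds a :class:`~medcea.parameters.ModelConfig` (or one joint
parameter draw from it) to the typed model objects and runs the full
deterministic pipeline. The probabilistic sensitivity analysis re-runs
exactly this code path once per draw, so the degenerate (all-fixed) Monte
Carlo reproduces the deterministic result bit for bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from . import economics
from .decision_model import AdeCascade, AdeModel, cascade
from .economics import CostEffectiveness, ProgramCosts, RoiResult
from .errors import NoTimingDataError
from .parameters import ModelConfig
from .trial_effect import EffectEstimate, Policy, TrialArmOutcome, estimate_effect


@dataclass(frozen=True)
class ScenarioInputs:
    """One fully-specified model input point (deterministic or one PSA draw)."""

    drug: str
    control: TrialArmOutcome
    app: TrialArmOutcome
    ade: AdeModel
    costs: ProgramCosts
    annual_administrations: float
    icer_administrations: float
    wage_per_second: float = 0.0


@dataclass(frozen=True)
class DeterministicResult:
    """Everything the deterministic pipeline computes for one input point."""

    drug: str
    effect: EffectEstimate
    ade: AdeCascade
    cost_effectiveness: Optional[CostEffectiveness]
    roi: RoiResult
    roi_at_annual_volume: float
    benefit_per_admin: float
    annual_cost: float


def scenario_inputs(
    config: ModelConfig, values: Optional[Mapping[str, float]] = None
) -> ScenarioInputs:
    """Bind parameter values (defaults: the means) to typed model inputs.

    ``values`` uses the canonical names of :meth:`ModelConfig.parameters`;
    the Cat E probability is derived as the complement of the (possibly
    sampled) Cat F probability.
    """
    v = dict(config.mean_values())
    if values is not None:
        v.update(values)

    def arm(name: str, cfg_arm) -> TrialArmOutcome:
        return TrialArmOutcome(
            n_administrations=v[f"{name}_n_administrations"],
            n_overdose=v[f"{name}_overdoses"],
            n_underdose=v[f"{name}_underdoses"],
            prep_time_mean_s=v.get(f"{name}_prep_time_s"),
            prep_time_sd_s=cfg_arm.prep_time_sd_s,
        )

    training = tuple(
        (g.label, v[f"training_{g.label}"]) for g in config.costs.training_groups
    )
    dev = config.costs.development_cost
    return ScenarioInputs(
        drug=config.drug,
        control=arm("control", config.trial.control),
        app=arm("app", config.trial.app),
        ade=AdeModel(
            p_ade=v["p_ade"],
            p_cat_f=v["p_cat_f"],
            clos_days=v["clos_days"],
            daily_cost=v["daily_cost"],
            excess_complication_cost=v["excess_complication_cost"],
            excess_fraction=config.ade.excess_fraction,
            cat_e_cost_formulation=config.cat_e_cost_formulation,
        ),
        costs=ProgramCosts(
            maintenance_annual=v["maintenance_annual"],
            training=training,
            device_annual=v["device_annual"],
            development_cost=None if dev is None else dev.value,
        ),
        annual_administrations=float(config.annual_administrations),
        icer_administrations=float(config.icer_administrations),
        wage_per_second=v.get("wage_per_second", 0.0),
    )


def evaluate(inputs: ScenarioInputs, policy: Policy = "pooled_denominator") -> DeterministicResult:
    """Run trial_effect -> decision_model -> economics on one input point.

    Robust to degenerate probabilistic draws: when the draw prevents no
    errors the cost-effectiveness ratios are undefined (reported as ``None``)
    and the ROI result carries the never-profitable signal instead of
    raising.
    """
    effect = estimate_effect(inputs.control, inputs.app, policy)
    casc = cascade(effect.err_per_admin, inputs.ade)
    annual_cost = economics.annual_program_cost(inputs.costs)

    time_saved = effect.time_saved_s
    if inputs.wage_per_second > 0 and time_saved is None:
        raise NoTimingDataError(
            "wage_per_second is set but the trial arms carry no timing data"
        )
    time_value = (time_saved or 0.0) * inputs.wage_per_second

    ce: Optional[CostEffectiveness]
    if effect.err_per_admin > 0 and inputs.icer_administrations > 0:
        ce = economics.cost_effectiveness(
            annual_cost,
            inputs.icer_administrations,
            effect.err_per_admin,
            inputs.ade.p_ade,
            time_value_offset=time_value,
        )
    else:
        ce = None

    benefit = economics.benefit_per_admin(
        effect.err_per_admin,
        inputs.ade.p_ade,
        casc.expected_cost_per_ade,
        time_saved_s=time_saved or 0.0,
        wage_per_second=inputs.wage_per_second,
    )
    roi = economics.breakeven_administrations(annual_cost, benefit)
    roi_at_volume = economics.roi_at_volume(
        annual_cost, benefit, inputs.annual_administrations
    )
    return DeterministicResult(
        drug=inputs.drug,
        effect=effect,
        ade=casc,
        cost_effectiveness=ce,
        roi=roi,
        roi_at_annual_volume=roi_at_volume,
        benefit_per_admin=benefit,
        annual_cost=annual_cost,
    )


def run_deterministic(
    config: ModelConfig, policy: Policy = "pooled_denominator"
) -> DeterministicResult:
    """Evaluate the scenario at every parameter's mean."""
    return evaluate(scenario_inputs(config), policy)
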