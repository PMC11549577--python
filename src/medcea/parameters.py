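"""Model parameters, uncertainty distributions, and scenario configuration.

A scenario is a typed, validated configuration (YAML or JSON) holding, for
one drug, the trial evidence (arm sizes, overdose/underdose counts,
preparation-time summaries), the adverse-drug-event (ADE) cascade
probabilities and unit costs, the annual program costs of running the app,
and per-parameter uncertainty distributions used by the probabilistic
sensitivity analysis.

Conventions
-----------
* All monetary amounts are US dollars at the 2019 price level. Amounts
  given in CHF are converted once, at load time, with the configured
  exchange rate (CHF 1 = US $1.03 at the end of 2019).
* Every scalar parameter carries a :class:`DistributionSpec`. A parameter
  with no stated distribution is ``fixed`` and always samples to its mean.
* Uniform distributions with no stated support default to the +/-20% rule:
  support exactly ``[0.8 * mean, 1.2 * mean]``.
* Sampling respects optional truncation limits by rejection (redraw), never
  by clipping, so truncated draws carry no point mass at the bounds.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError, DomainError

logger = logging.getLogger(__name__)

_MAX_REJECTION_TRIES = 100_000


class DistributionSpec(BaseModel):
    """How one scalar parameter varies under uncertainty.

    ``kind`` is one of ``fixed`` (degenerate at the mean), ``normal``
    (``mean``/``sd``), or ``uniform`` (``low``/``high``; auto-filled to
    ``0.8*mean``..``1.2*mean`` when omitted). ``lower_bound``/``upper_bound``
    are truncation limits in the parameter's natural range (e.g. [0, 1] for
    probabilities) enforced by rejection sampling. ``ci_low``/``ci_high``
    optionally record a published 95% CI; when present they are used
    verbatim as the one-way (tornado) endpoints of normal parameters.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["fixed", "normal", "uniform"] = "fixed"
    mean: Optional[float] = None
    sd: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @model_validator(mode="after")
    def _basic_invariants(self) -> "DistributionSpec":
        if self.kind == "normal" and self.sd is not None and self.sd < 0:
            raise ValueError("normal distribution requires sd >= 0")
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and not self.lower_bound < self.upper_bound
        ):
            raise ValueError("truncation limits must satisfy lower_bound < upper_bound")
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError("uniform support must satisfy low <= high")
        return self

    # -- construction helpers -------------------------------------------------

    @classmethod
    def fixed(cls, mean: float) -> "DistributionSpec":
        return cls(kind="fixed", mean=mean)

    @classmethod
    def uniform_pm20(cls, mean: float, **kw) -> "DistributionSpec":
        """Uniform under the +/-20% rule: support [0.8*mean, 1.2*mean]."""
        return cls(kind="uniform", mean=mean, low=0.8 * mean, high=1.2 * mean, **kw)

    @classmethod
    def normal(cls, mean: float, sd: float, **kw) -> "DistributionSpec":
        return cls(kind="normal", mean=mean, sd=sd, **kw)

    def bind(self, mean: float) -> "DistributionSpec":
        """Return a complete copy with the mean filled in.

        A uniform spec with no explicit support gets the +/-20% rule.
        Raises :class:`ConfigError` if the completed spec is inconsistent.
        """
        d = self.model_copy(update={"mean": self.mean if self.mean is not None else mean})
        if d.kind == "uniform" and d.low is None and d.high is None:
            d = d.model_copy(update={"low": 0.8 * d.mean, "high": 1.2 * d.mean})
        d.validate_complete()
        return d

    def validate_complete(self) -> None:
        """Check invariants that need a bound mean."""
        if self.mean is None:
            raise ConfigError("distribution has no mean bound to it")
        if self.kind == "normal" and self.sd is None:
            raise ConfigError("normal distribution requires sd")
        if self.kind == "uniform":
            if self.low is None or self.high is None:
                raise ConfigError("uniform distribution requires low/high (or the ±20% rule)")
            if not (self.low <= self.mean <= self.high):
                raise ConfigError(
                    f"uniform support [{self.low}, {self.high}] does not contain mean {self.mean}"
                )

    # -- behaviour ------------------------------------------------------------

    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed"

    def _in_bounds(self, x: float) -> bool:
        if self.lower_bound is not None and x < self.lower_bound:
            return False
        if self.upper_bound is not None and x > self.upper_bound:
            return False
        return True

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; truncation limits enforced by rejection."""
        self.validate_complete()
        if self.kind == "fixed":
            return float(self.mean)
        for _ in range(_MAX_REJECTION_TRIES):
            if self.kind == "uniform":
                x = float(rng.uniform(self.low, self.high))
            else:
                x = float(rng.normal(self.mean, self.sd))
            if self._in_bounds(x):
                return x
        raise DomainError(
            f"rejection sampling failed: truncation limits "
            f"[{self.lower_bound}, {self.upper_bound}] carry almost no mass"
        )

    def tornado_bounds(self) -> tuple[float, float]:
        """Low/high inputs for one-way sensitivity analysis.

        Fixed parameters get a zero-width bar. Uniform parameters use the
        support endpoints. Normal parameters use the published 95% CI when
        configured, otherwise mean +/- 1.96*sd, truncated to the natural
        bounds.
        """
        self.validate_complete()
        if self.kind == "fixed":
            return float(self.mean), float(self.mean)
        if self.kind == "uniform":
            return float(self.low), float(self.high)
        if self.ci_low is not None and self.ci_high is not None:
            lo, hi = float(self.ci_low), float(self.ci_high)
        else:
            lo = self.mean - 1.96 * self.sd
            hi = self.mean + 1.96 * self.sd
        if self.lower_bound is not None:
            lo = max(lo, self.lower_bound)
        if self.upper_bound is not None:
            hi = min(hi, self.upper_bound)
        return lo, hi

    def scaled(self, factor: float) -> "DistributionSpec":
        """Rescale the whole distribution (used for currency conversion)."""
        if factor <= 0:
            raise DomainError("scale factor must be positive")

        def s(v: Optional[float]) -> Optional[float]:
            return None if v is None else v * factor

        return self.model_copy(
            update={
                "mean": s(self.mean),
                "sd": s(self.sd),
                "low": s(self.low),
                "high": s(self.high),
                "lower_bound": s(self.lower_bound),
                "upper_bound": s(self.upper_bound),
                "ci_low": s(self.ci_low),
                "ci_high": s(self.ci_high),
            }
        )


@dataclass(frozen=True)
class Money:
    """An amount in a named currency at a reference price year."""

    amount: float
    currency: Literal["CHF", "USD"] = "USD"
    year: int = 2019


def to_usd(x: Money, rate: float) -> Money:
    """Convert CHF to USD at ``rate`` USD per CHF; USD passes through."""
    if rate <= 0:
        raise DomainError(f"exchange rate must be positive, got {rate}")
    if x.currency == "USD":
        return x
    return Money(amount=x.amount * rate, currency="USD", year=x.year)


@dataclass(frozen=True)
class Parameter:
    """A named scalar model input with its uncertainty distribution.

    ``value`` is the point (mean) value in USD / natural units after any
    currency conversion; ``distribution`` is complete (mean bound).
    """

    name: str
    value: float
    distribution: DistributionSpec
    units: str = ""
    source: str = ""

    def sample(self, rng: np.random.Generator) -> float:
        return self.distribution.sample(rng)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------


class ParamField(BaseModel):
    """One configurable scalar: value, currency, and distribution.

    In YAML a bare number is shorthand for a fixed parameter:
    ``device_annual: 0.0`` == ``device_annual: {value: 0.0}``.
    """

    model_config = ConfigDict(extra="forbid")

    value: float
    currency: Literal["USD", "CHF"] = "USD"
    units: str = ""
    source: str = ""
    distribution: DistributionSpec = Field(default_factory=DistributionSpec)

    @model_validator(mode="before")
    @classmethod
    def _coerce_scalar(cls, v):
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            return {"value": float(v)}
        return v

    def to_parameter(self, name: str, rate: float = 1.03) -> Parameter:
        value = self.value
        dist = self.distribution
        if self.currency == "CHF":
            value = to_usd(Money(value, "CHF"), rate).amount
            dist = dist.scaled(rate)
        try:
            bound = dist.bind(value)
        except ConfigError as exc:
            raise ConfigError(f"parameter {name!r}: {exc}") from exc
        return Parameter(name=name, value=value, distribution=bound,
                         units=self.units, source=self.source)


class TrialArmConfig(BaseModel):
    """One trial arm: administrations, error counts, timing summary."""

    model_config = ConfigDict(extra="forbid")

    n_administrations: int = Field(ge=1)
    overdoses: ParamField
    underdoses: ParamField
    prep_time_mean_s: Optional[ParamField] = None
    prep_time_sd_s: Optional[float] = Field(default=None, ge=0)
    reported_errors: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _counts_fit(self) -> "TrialArmConfig":
        if self.overdoses.value < 0 or self.underdoses.value < 0:
            raise ValueError("error counts must be non-negative")
        if self.overdoses.value + self.underdoses.value > self.n_administrations:
            raise ValueError("overdoses + underdoses exceed administrations")
        return self


class TrialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control: TrialArmConfig
    app: TrialArmConfig


class AdeConfig(BaseModel):
    """ADE cascade probabilities and unit costs.

    Only ``p_cat_f`` is an uncertain parameter; ``p_cat_e`` is derived as
    its complement so the two category probabilities always sum to one.
    A configured ``p_cat_e`` is accepted for documentation but must equal
    ``1 - p_cat_f`` at the mean.
    """

    model_config = ConfigDict(extra="forbid")

    p_ade: ParamField
    p_cat_f: ParamField
    p_cat_e: Optional[ParamField] = None
    clos_days: ParamField
    daily_cost: ParamField
    excess_complication_cost: ParamField
    excess_fraction: float = Field(default=0.9184, gt=0)

    @model_validator(mode="after")
    def _probabilities(self) -> "AdeConfig":
        for name in ("p_ade", "p_cat_f"):
            v = getattr(self, name).value
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_cat_e is not None:
            if abs(self.p_cat_e.value + self.p_cat_f.value - 1.0) > 1e-9:
                raise ValueError("p_cat_e must equal 1 - p_cat_f")
        return self


class TrainingGroup(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    annual_total_cost: ParamField


class CostsConfig(BaseModel):
    """Annual app-side program costs.

    ``maintenance_annual`` defaults to 20% of the development cost when
    omitted. The development cost itself is reference only and never enters
    the cost-effectiveness ratios.
    """

    model_config = ConfigDict(extra="forbid")

    development_cost: Optional[ParamField] = None
    maintenance_annual: Optional[ParamField] = None
    training_groups: list[TrainingGroup] = Field(default_factory=list)
    device_annual: ParamField = Field(default_factory=lambda: ParamField(value=0.0))

    @model_validator(mode="after")
    def _derive_maintenance(self) -> "CostsConfig":
        if self.maintenance_annual is None:
            if self.development_cost is None:
                raise ValueError(
                    "either maintenance_annual or development_cost must be given"
                )
            m = 0.2 * self.development_cost.value
            self.maintenance_annual = ParamField(
                value=m,
                currency=self.development_cost.currency,
                distribution=DistributionSpec(kind="uniform"),
                source="derived: 20% of development cost",
            )
        labels = [g.label for g in self.training_groups]
        if len(labels) != len(set(labels)):
            raise ValueError("training group labels must be unique")
        for f in (self.maintenance_annual, self.device_annual):
            if f.value < 0:
                raise ValueError("program costs must be non-negative")
        return self


class PsaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    draws: int = Field(default=10_000, ge=1)
    seed: int = 20190101


class ModelConfig(BaseModel):
    """Complete, validated scenario for one drug.

    ``annual_administrations`` is the yearly volume at the implementing unit
    (used for ROI-at-volume); ``icer_administrations`` is the volume in the
    ICER denominator and defaults to the same number. The two are kept
    separate because published cost-per-error figures can imply a different
    volume than the published unit volume; a warning is logged when they
    differ.
    """

    model_config = ConfigDict(extra="forbid")

    drug: str
    route: Literal["direct_iv", "continuous_infusion"]
    trial: TrialConfig
    ade: AdeConfig
    costs: CostsConfig
    annual_administrations: int = Field(ge=0)
    icer_administrations: Optional[int] = Field(default=None, ge=0)
    cat_e_cost_formulation: Literal["excess_only", "stay_plus_excess"] = "excess_only"
    wage_per_second: ParamField = Field(default_factory=lambda: ParamField(value=0.0))
    exchange_rate: ParamField = Field(default_factory=lambda: ParamField(value=1.03))
    currency_year: int = 2019
    psa: PsaConfig = Field(default_factory=PsaConfig)

    @model_validator(mode="after")
    def _fill_defaults(self) -> "ModelConfig":
        if self.exchange_rate.value <= 0:
            raise ValueError("exchange rate must be positive")
        if self.icer_administrations is None:
            self.icer_administrations = self.annual_administrations
        return self

    # -- parameter table ------------------------------------------------------

    @property
    def rate(self) -> float:
        return self.exchange_rate.value

    def parameters(self) -> dict[str, Parameter]:
        """All scalar parameters in canonical (sampling) order, USD-converted.

        The order is fixed so that seeded Monte Carlo draws are reproducible
        for a given configuration.
        """
        rate = self.rate
        params: dict[str, Parameter] = {}

        def add(name: str, pf: Optional[ParamField]) -> None:
            if pf is not None:
                params[name] = pf.to_parameter(name, rate)

        for arm_name in ("control", "app"):
            arm: TrialArmConfig = getattr(self.trial, arm_name)
            params[f"{arm_name}_n_administrations"] = Parameter(
                name=f"{arm_name}_n_administrations",
                value=float(arm.n_administrations),
                distribution=DistributionSpec.fixed(float(arm.n_administrations)),
                units="administrations",
            )
            add(f"{arm_name}_overdoses", arm.overdoses)
            add(f"{arm_name}_underdoses", arm.underdoses)
            add(f"{arm_name}_prep_time_s", arm.prep_time_mean_s)
        add("p_ade", self.ade.p_ade)
        add("p_cat_f", self.ade.p_cat_f)
        add("clos_days", self.ade.clos_days)
        add("daily_cost", self.ade.daily_cost)
        add("excess_complication_cost", self.ade.excess_complication_cost)
        add("maintenance_annual", self.costs.maintenance_annual)
        for group in self.costs.training_groups:
            add(f"training_{group.label}", group.annual_total_cost)
        add("device_annual", self.costs.device_annual)
        add("wage_per_second", self.wage_per_second)
        add("exchange_rate", self.exchange_rate)
        return params

    def mean_values(self) -> dict[str, float]:
        return {name: p.value for name, p in self.parameters().items()}

    def sample_values(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint draw: every parameter sampled once, in canonical order.

        Parameters are mutually independent; the Cat E probability is the
        enforced complement of the sampled Cat F probability downstream.
        """
        return {name: p.sample(rng) for name, p in self.parameters().items()}


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a complete distribution spec."""
    return spec.sample(rng)


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def config_from_dict(raw: dict) -> ModelConfig:
    try:
        cfg = ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid scenario configuration: {_format_validation_error(exc)}") from exc
    _warn_inconsistencies(cfg)
    return cfg


def _warn_inconsistencies(cfg: ModelConfig) -> None:
    for arm_name in ("control", "app"):
        arm = getattr(cfg.trial, arm_name)
        if arm.reported_errors is not None:
            counted = arm.overdoses.value + arm.underdoses.value
            if abs(arm.reported_errors - counted) > 1e-9:
                logger.warning(
                    "%s/%s arm: reported error total %s differs from "
                    "overdoses+underdoses = %s; the model uses the component counts",
                    cfg.drug, arm_name, arm.reported_errors, counted,
                )
    if cfg.icer_administrations != cfg.annual_administrations:
        logger.warning(
            "%s: icer_administrations (%d) differs from annual_administrations (%d); "
            "cost-per-error uses the former, ROI-at-volume the latter",
            cfg.drug, cfg.icer_administrations, cfg.annual_administrations,
        )


def load_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a scenario file (YAML or JSON).

    Raises :class:`ConfigError` naming the offending field on invalid
    content, or the parse position on malformed text.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping at the top level")
    return config_from_dict(raw)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a config back to YAML or JSON (round-trips with load_config)."""
    path = Path(path)
    raw = cfg.model_dump(mode="json", exclude_none=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


def packaged_config_path(name: str) -> Path:
    """Path of a config shipped with the package (e.g. ``epinephrine_2019``)."""
    from importlib.resources import files

    base = files("medcea") / "configs"
    candidate = base / (name if name.endswith((".yaml", ".json")) else f"{name}.yaml")
    p = Path(str(candidate))
    if not p.exists():
        available = sorted(q.name for q in Path(str(base)).glob("*.yaml"))
        raise ConfigError(f"no packaged config {name!r}; available: {available}")
    return p


def load_packaged_config(name: str) -> ModelConfig:
    return load_config(packaged_config_path(name))


def list_packaged_configs() -> list[str]:
    from importlib.resources import files

    base = Path(str(files("medcea") / "configs"))
    return sorted(p.stem for p in base.glob("*.yaml"))
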