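"""Probabilistic (Monte Carlo) and deterministic (tornado) sensitivity analysis.

``run_psa`` propagates parameter uncertainty by sampling every non-fixed
parameter once per draw and re-running the full deterministic pipeline;
``tornado`` moves one parameter at a time between its low and high bounds
while all others sit at their means. Both operate on any named scalar
outcome of the pipeline (break-even administrations by default).

Percentiles are empirical nearest-rank order statistics — no interpolation
or smoothing — so the reported "95% of simulations" value is an actual
simulated draw.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .parameters import DistributionSpec, ModelConfig, Parameter
from .pipeline import DeterministicResult, evaluate, scenario_inputs

logger = logging.getLogger(__name__)

#: Scalar outcomes the sensitivity analyses can target, extracted from a
#: pipeline result. Undefined values (no errors prevented / never
#: profitable) surface as inf and are segregated by the PSA.
OUTCOME_FNS: dict[str, Callable[[DeterministicResult], float]] = {
    "breakeven_administrations": lambda r: r.roi.breakeven_real,
    "cost_per_error": lambda r: (
        r.cost_effectiveness.cost_per_error if r.cost_effectiveness else math.inf
    ),
    "cost_per_ade": lambda r: (
        r.cost_effectiveness.cost_per_ade if r.cost_effectiveness else math.inf
    ),
    "benefit_per_admin": lambda r: r.benefit_per_admin,
    "roi_at_annual_volume": lambda r: r.roi_at_annual_volume,
}

PERCENTILES = (2.5, 5.0, 50.0, 95.0, 97.5)


@dataclass(frozen=True)
class PsaResult:
    """Seeded Monte Carlo draws of one scalar outcome plus summaries.

    ``draws`` holds every draw in order (``inf`` marks never-profitable
    draws); ``n_never_profitable`` counts them. Summary statistics and
    percentiles are computed over the finite draws only.
    """

    outcome_name: str
    draws: np.ndarray
    n_draws: int
    seed: int
    n_never_profitable: int
    mean: float
    sd: float
    percentiles: dict[float, float]
    samples: Optional[pd.DataFrame] = None

    @property
    def finite_draws(self) -> np.ndarray:
        return self.draws[np.isfinite(self.draws)]


@dataclass(frozen=True)
class CumulativeCurve:
    """Fraction of draws achieving positive ROI at or below each volume."""

    grid: np.ndarray
    cum_fraction: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_administrations": self.grid, "cum_fraction": self.cum_fraction}
        )


@dataclass(frozen=True)
class TornadoResult:
    """One-way sensitivity table, widest bar first."""

    outcome_name: str
    outcome_at_means: float
    table: pd.DataFrame  # name, low_input, high_input, outcome_at_low/high, range


def nearest_rank_percentile(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Empirical nearest-rank percentile: the ceil(q/100 * n)-th order statistic."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise DomainError("percentile of an empty sample")
    if not 0.0 < q <= 100.0:
        raise DomainError(f"percentile level must lie in (0, 100], got {q}")
    k = max(1, math.ceil(q / 100.0 * n))
    return float(x[k - 1])


def monte_carlo(
    specs: Mapping[str, DistributionSpec],
    outcome_fn: Callable[[Mapping[str, float]], float],
    n_draws: int,
    seed: int,
    outcome_name: str = "outcome",
    record_samples: bool = False,
) -> PsaResult:
    """Generic seeded Monte Carlo over independent parameter distributions.

    Parameters are sampled in the mapping's iteration order with a single
    ``numpy`` Generator, so identical (specs, n_draws, seed) give identical
    draws.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws, dtype=float)
    rows: list[dict[str, float]] = []
    for i in range(n_draws):
        values = {name: spec.sample(rng) for name, spec in specs.items()}
        draws[i] = outcome_fn(values)
        if record_samples:
            rows.append(values)

    finite = draws[np.isfinite(draws)]
    n_bad = int(n_draws - finite.size)
    if n_bad:
        logger.warning(
            "%d of %d draws were never profitable; they are counted separately "
            "and excluded from the percentiles",
            n_bad, n_draws,
        )
    if finite.size == 0:
        mean = sd = math.nan
        pct = {q: math.nan for q in PERCENTILES}
    else:
        mean = float(finite.mean())
        sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        pct = {q: nearest_rank_percentile(finite, q) for q in PERCENTILES}
    samples = None
    if record_samples:
        samples = pd.DataFrame(rows)
        samples.insert(0, "draw_index", np.arange(n_draws))
        samples[outcome_name] = draws
    return PsaResult(
        outcome_name=outcome_name,
        draws=draws,
        n_draws=n_draws,
        seed=seed,
        n_never_profitable=n_bad,
        mean=mean,
        sd=sd,
        percentiles=pct,
        samples=samples,
    )


def run_psa(
    config: ModelConfig,
    n_draws: Optional[int] = None,
    seed: Optional[int] = None,
    outcome: str = "breakeven_administrations",
    record_samples: bool = False,
) -> PsaResult:
    """Probabilistic sensitivity analysis of one scenario.

    Every non-fixed parameter is sampled once per draw (mutually
    independent; the Cat E probability is the enforced complement of the
    sampled Cat F probability) and the full deterministic pipeline is
    re-evaluated. Defaults for draws and seed come from the config's
    ``psa`` block.
    """
    if outcome not in OUTCOME_FNS:
        raise DomainError(
            f"unknown outcome {outcome!r}; available: {sorted(OUTCOME_FNS)}"
        )
    extract = OUTCOME_FNS[outcome]
    specs = {name: p.distribution for name, p in config.parameters().items()}

    def outcome_fn(values: Mapping[str, float]) -> float:
        return extract(evaluate(scenario_inputs(config, values)))

    return monte_carlo(
        specs,
        outcome_fn,
        n_draws=n_draws if n_draws is not None else config.psa.draws,
        seed=seed if seed is not None else config.psa.seed,
        outcome_name=outcome,
        record_samples=record_samples,
    )


def positive_roi_fraction_by_n(psa: PsaResult, max_n: int) -> CumulativeCurve:
    """Cumulative fraction of draws whose break-even volume is <= n.

    Never-profitable draws (``inf``) never clear any threshold, so they
    depress the curve's plateau below one.
    """
    if max_n < 1:
        raise DomainError("max_n must be >= 1")
    grid = np.arange(1, max_n + 1)
    draws = psa.draws
    cum = np.array([(draws <= n).mean() for n in grid])
    return CumulativeCurve(grid=grid, cum_fraction=cum)


def tornado_table(
    parameters: Mapping[str, Parameter],
    outcome_fn: Callable[[Mapping[str, float]], float],
) -> pd.DataFrame:
    """One-way sensitivity over a parameter table (generic core).

    Each parameter is set in turn to its low and high tornado bound while
    all the others stay at their means; fixed parameters get zero-width
    bars. Rows are sorted by descending range (stable, so ties keep the
    canonical parameter order).
    """
    means = {name: p.value for name, p in parameters.items()}
    rows = []
    for name, p in parameters.items():
        lo, hi = p.distribution.tornado_bounds()
        at_lo = outcome_fn({**means, name: lo})
        at_hi = outcome_fn({**means, name: hi})
        rows.append(
            {
                "name": name,
                "low_input": lo,
                "high_input": hi,
                "outcome_at_low": at_lo,
                "outcome_at_high": at_hi,
                "range": abs(at_hi - at_lo),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("range", ascending=False, kind="stable").reset_index(drop=True)


def tornado(config: ModelConfig, outcome: str = "breakeven_administrations") -> TornadoResult:
    """Tornado analysis of one scenario on a named outcome."""
    if outcome not in OUTCOME_FNS:
        raise DomainError(
            f"unknown outcome {outcome!r}; available: {sorted(OUTCOME_FNS)}"
        )
    extract = OUTCOME_FNS[outcome]

    def outcome_fn(values: Mapping[str, float]) -> float:
        return extract(evaluate(scenario_inputs(config, values)))

    params = config.parameters()
    at_means = outcome_fn({name: p.value for name, p in params.items()})
    return TornadoResult(
        outcome_name=outcome,
        outcome_at_means=at_means,
        table=tornado_table(params, outcome_fn),
    )
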