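"""Scenario execution, report tables, and provenance.

``run_scenario`` executes the deterministic pipeline, the probabilistic
sensitivity analysis and the tornado analysis for one configuration and
(optionally) writes the results as CSV/JSON files. Every result carries a
provenance block (config hash, seed, formulation, package version) so any
reported number is traceable to a configuration plus a seed.

Rounding happens at reporting time only: per-administration ratios to 3
decimals, money to whole dollars, break-even volumes to 1 decimal plus the
integer ceiling. Raw precision is preserved in the JSON output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigError
from .parameters import ModelConfig
from .pipeline import DeterministicResult, run_deterministic
from .uncertainty import (
    CumulativeCurve,
    PsaResult,
    TornadoResult,
    positive_roi_fraction_by_n,
    run_psa,
    tornado,
)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (spreadsheet-style), for report formatting."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def config_hash(config: ModelConfig) -> str:
    """Stable content hash of a scenario configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ScenarioResult:
    """All computed outputs for one drug scenario, with provenance."""

    drug: str
    config: ModelConfig
    deterministic: DeterministicResult
    psa: Optional[PsaResult]
    curve: Optional[CumulativeCurve]
    tornado: Optional[TornadoResult]
    seed: int
    provenance: dict

    def effectiveness_row(self) -> dict:
        """One row of the cost-effectiveness table (rounded for reporting)."""
        d = self.deterministic
        ce = d.cost_effectiveness
        return {
            "drug": self.drug,
            "route": self.config.route,
            "err_per_admin": round_half_up(d.effect.err_per_admin, 3),
            "ade_per_admin": round_half_up(d.ade.n_ade, 3),
            "cost_per_error_usd": None if ce is None else round_half_up(ce.cost_per_error),
            "cost_per_ade_usd": None if ce is None else round_half_up(ce.cost_per_ade),
        }

    def roi_row(self) -> dict:
        """One row of the break-even / ROI table (rounded for reporting)."""
        d = self.deterministic
        p95 = None
        if self.psa is not None:
            p95 = self.psa.percentiles.get(95.0)
        return {
            "drug": self.drug,
            "breakeven_admin": d.roi.breakeven_int,
            "breakeven_admin_real": round_half_up(d.roi.breakeven_real, 1)
            if not d.roi.never_profitable
            else math.inf,
            "psa_p95_breakeven": None if p95 is None else round_half_up(p95, 1),
            "annual_administrations": self.config.annual_administrations,
            "roi_at_annual_volume": round_half_up(d.roi_at_annual_volume, 2),
        }


def _provenance(config: ModelConfig, seed: int, draws: int) -> dict:
    return {
        "config_hash": config_hash(config),
        "drug": config.drug,
        "seed": seed,
        "psa_draws": draws,
        "cat_e_cost_formulation": config.cat_e_cost_formulation,
        "icer_administrations": config.icer_administrations,
        "annual_administrations": config.annual_administrations,
        "package_version": __version__,
    }


def run_scenario(
    config: ModelConfig,
    draws: Optional[int] = None,
    seed: Optional[int] = None,
    formulation: Optional[str] = None,
    with_psa: bool = True,
    with_tornado: bool = True,
    curve_max_n: Optional[int] = None,
) -> ScenarioResult:
    """Execute the full analysis for one scenario.

    ``formulation`` overrides the config's Cat E cost formulation; the
    choice is always recorded in the provenance block because it changes
    every benefit-side quantity.
    """
    if formulation is not None:
        config = config.model_copy(update={"cat_e_cost_formulation": formulation})
    n_draws = draws if draws is not None else config.psa.draws
    psa_seed = seed if seed is not None else config.psa.seed

    det = run_deterministic(config)
    psa = curve = torn = None
    if with_psa:
        psa = run_psa(config, n_draws=n_draws, seed=psa_seed)
        if curve_max_n is None:
            finite = psa.finite_draws
            top = float(finite.max()) if finite.size else 50.0
            curve_max_n = max(10, int(math.ceil(top)))
        curve = positive_roi_fraction_by_n(psa, curve_max_n)
    if with_tornado:
        torn = tornado(config)
    return ScenarioResult(
        drug=config.drug,
        config=config,
        deterministic=det,
        psa=psa,
        curve=curve,
        tornado=torn,
        seed=psa_seed,
        provenance=_provenance(config, psa_seed, n_draws if with_psa else 0),
    )


def compare_drugs(results: Sequence[ScenarioResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine scenarios into cost-effectiveness and ROI tables."""
    names = [r.drug for r in results]
    if len(names) != len(set(names)):
        raise ConfigError(f"duplicate drug names in comparison: {names}")
    eff = pd.DataFrame([r.effectiveness_row() for r in results])
    roi = pd.DataFrame([r.roi_row() for r in results])
    return eff, roi


def _full_precision_dict(result: ScenarioResult) -> dict:
    d = result.deterministic
    out = {
        "provenance": result.provenance,
        "effect": dataclasses.asdict(d.effect),
        "ade_cascade": dataclasses.asdict(d.ade),
        "annual_cost": d.annual_cost,
        "benefit_per_admin": d.benefit_per_admin,
        "roi": dataclasses.asdict(d.roi),
        "roi_at_annual_volume": d.roi_at_annual_volume,
        "cost_effectiveness": (
            None
            if d.cost_effectiveness is None
            else dataclasses.asdict(d.cost_effectiveness)
        ),
    }
    if result.psa is not None:
        out["psa"] = {
            "outcome": result.psa.outcome_name,
            "n_draws": result.psa.n_draws,
            "seed": result.psa.seed,
            "n_never_profitable": result.psa.n_never_profitable,
            "mean": result.psa.mean,
            "sd": result.psa.sd,
            "percentiles": {str(k): v for k, v in result.psa.percentiles.items()},
        }
    return out


def _json_default(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON serializable: {obj!r}")


def write_outputs(result: ScenarioResult, outdir: str | Path, make_plots: bool = False) -> list[Path]:
    """Write CSV/JSON reports (and optional plots) for one scenario.

    Outputs carry no timestamps, so identical config + seed reproduces every
    file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = result.drug
    written: list[Path] = []

    eff, roi = compare_drugs([result])
    p = outdir / f"{stem}_cost_effectiveness.csv"
    eff.to_csv(p, index=False)
    written.append(p)
    p = outdir / f"{stem}_roi.csv"
    roi.to_csv(p, index=False)
    written.append(p)

    p = outdir / f"{stem}_result.json"
    payload = json.dumps(_full_precision_dict(result), indent=2, default=_json_default)
    p.write_text(payload + "\n")
    written.append(p)

    if result.psa is not None:
        draws = pd.DataFrame(
            {"draw_index": range(result.psa.n_draws), result.psa.outcome_name: result.psa.draws}
        )
        p = outdir / f"{stem}_psa_draws.csv"
        draws.to_csv(p, index=False)
        written.append(p)
    if result.curve is not None:
        p = outdir / f"{stem}_roi_cumulative.csv"
        result.curve.as_frame().to_csv(p, index=False)
        written.append(p)
    if result.tornado is not None:
        p = outdir / f"{stem}_tornado.csv"
        result.tornado.table.to_csv(p, index=False)
        written.append(p)

    if make_plots:
        from . import plots

        if result.psa is not None:
            p = outdir / f"{stem}_psa_hist.png"
            plots.plot_psa_histogram(result.psa, p)
            written.append(p)
        if result.curve is not None:
            p = outdir / f"{stem}_roi_cumulative.png"
            plots.plot_cumulative_curve(result.curve, p, title=result.drug)
            written.append(p)
        if result.tornado is not None:
            p = outdir / f"{stem}_tornado.png"
            plots.plot_tornado(result.tornado, p, title=result.drug)
            written.append(p)
    return written
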