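"""Synthetic per-administration trial data with the structure the model assumes.

The economic model consumes trial summaries (arm sizes, overdose/underdose
counts, preparation-time moments). This module generates the record-level
data underneath those summaries — one row per administration with an arm
label, a signed dose deviation relative to the prescribed weight-based
dose, and a preparation time — so the whole pipeline can be exercised and
parameter recovery demonstrated without any external data.

Generative model, per administration:

* the error class is multinomial over (overdose, underdose, correct) with
  arm-specific probabilities;
* overdoses draw a deviation uniformly in (+0.10, +1.0], underdoses in
  [-1.0, -0.10), correct doses in (-0.10, +0.10) — only the +/-10%
  threshold matters downstream, so the magnitudes are a modelling choice,
  not an empirical claim;
* preparation time is normal truncated at zero (rejection sampling).

The classification boundary is strict: a deviation of exactly +/-0.10 is
not an error.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .trial_effect import TrialArmOutcome

RECORD_COLUMNS = ("arm", "dose_deviation_fraction", "prep_time_s")
ERROR_THRESHOLD = 0.10


@dataclass(frozen=True)
class ArmTruth:
    """Ground-truth generative parameters for one arm."""

    p_overdose: float
    p_underdose: float
    prep_time_mean_s: float
    prep_time_sd_s: float
    n_administrations: int

    def __post_init__(self) -> None:
        if self.p_overdose < 0 or self.p_underdose < 0:
            raise DomainError("error probabilities must be non-negative")
        if self.p_overdose + self.p_underdose > 1.0:
            raise DomainError("p_overdose + p_underdose must not exceed 1")
        if self.prep_time_mean_s <= 0 or self.prep_time_sd_s < 0:
            raise DomainError("timing parameters must be positive")
        if self.n_administrations < 1:
            raise DomainError("each arm needs at least one administration")


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth for a two-arm trial plus the generator seed."""

    control: ArmTruth
    app: ArmTruth
    seed: int = 0

    @classmethod
    def from_counts(
        cls,
        control_od: float,
        control_ud: float,
        n_control: int,
        app_od: float,
        app_ud: float,
        n_app: int,
        control_time: tuple[float, float] = (201.1, 73.4),
        app_time: tuple[float, float] = (191.6, 80.3),
        seed: int = 0,
    ) -> "TrialTruth":
        """Truth whose per-arm error probabilities match observed counts."""
        return cls(
            control=ArmTruth(
                p_overdose=control_od / n_control,
                p_underdose=control_ud / n_control,
                prep_time_mean_s=control_time[0],
                prep_time_sd_s=control_time[1],
                n_administrations=n_control,
            ),
            app=ArmTruth(
                p_overdose=app_od / n_app,
                p_underdose=app_ud / n_app,
                prep_time_mean_s=app_time[0],
                prep_time_sd_s=app_time[1],
                n_administrations=n_app,
            ),
            seed=seed,
        )


def _truncated_normal_at_zero(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws conditioned on being positive, by rejection."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
        tries += 1
        if tries > 10_000:
            raise DomainError("timing distribution has almost no positive mass")
    return out


def _simulate_arm(rng: np.random.Generator, arm: str, truth: ArmTruth) -> pd.DataFrame:
    n = truth.n_administrations
    u = rng.random(n)
    overdose = u < truth.p_overdose
    underdose = (u >= truth.p_overdose) & (u < truth.p_overdose + truth.p_underdose)
    correct = ~(overdose | underdose)

    dev = np.empty(n)
    # open interval above the threshold so the strict classifier always fires
    dev[overdose] = rng.uniform(np.nextafter(ERROR_THRESHOLD, 1.0), 1.0, int(overdose.sum()))
    dev[underdose] = -rng.uniform(np.nextafter(ERROR_THRESHOLD, 1.0), 1.0, int(underdose.sum()))
    dev[correct] = rng.uniform(
        -ERROR_THRESHOLD + 1e-12, ERROR_THRESHOLD - 1e-12, int(correct.sum())
    )
    times = _truncated_normal_at_zero(rng, truth.prep_time_mean_s, truth.prep_time_sd_s, n)
    return pd.DataFrame(
        {"arm": arm, "dose_deviation_fraction": dev, "prep_time_s": times}
    )


def simulate_trial(truth: TrialTruth, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one synthetic trial as a per-administration record table.

    Identical (truth, seed) always produces an identical table. The control
    arm is generated first, then the app arm.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    frames = [
        _simulate_arm(rng, "control", truth.control),
        _simulate_arm(rng, "app", truth.app),
    ]
    return pd.concat(frames, ignore_index=True)


def classify(dose_deviation_fraction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(is_overdose, is_underdose) masks under the strict +/-10% rule."""
    dev = np.asarray(dose_deviation_fraction, dtype=float)
    return dev > ERROR_THRESHOLD, dev < -ERROR_THRESHOLD


def estimate_arm_outcomes(
    records: pd.DataFrame,
) -> tuple[TrialArmOutcome, TrialArmOutcome]:
    """Summarize a record table into (control, app) arm outcomes.

    Inverse of :func:`simulate_trial`: errors are counted with the strict
    +/-10% rule and timing is summarized with the sample mean and SD
    (ddof=1; SD is 0 for a single record).
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise DomainError(f"record table is missing columns: {missing}")
    arms = {}
    for arm in ("control", "app"):
        sub = records[records["arm"] == arm]
        if sub.empty:
            raise DomainError(f"record table has no rows for the {arm!r} arm")
        od, ud = classify(sub["dose_deviation_fraction"].to_numpy())
        times = sub["prep_time_s"].to_numpy(dtype=float)
        arms[arm] = TrialArmOutcome(
            n_administrations=float(len(sub)),
            n_overdose=float(od.sum()),
            n_underdose=float(ud.sum()),
            prep_time_mean_s=float(times.mean()),
            prep_time_sd_s=float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        )
    return arms["control"], arms["app"]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path} is missing columns: {missing}")
    return df
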