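"""Figure mirrors: PSA histogram with cumulative overlay, cumulative ROI
curve, and tornado bars. Matplotlib with the non-interactive backend."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import CumulativeCurve, PsaResult, TornadoResult


def plot_psa_histogram(psa: PsaResult, path: str | Path, title: str = "") -> None:
    """Frequency of simulated outcomes with the cumulative frequency overlaid."""
    x = psa.finite_draws
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(x, bins=40, color="0.2", label="frequency")
    ax2 = ax.twinx()
    xs = np.sort(x)
    ax2.plot(xs, np.arange(1, xs.size + 1) / xs.size, color="0.6", label="cumulative")
    ax2.set_ylim(0, 1.02)
    ax.set_xlabel(psa.outcome_name)
    ax.set_ylabel("simulations")
    ax2.set_ylabel("cumulative fraction")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative_curve(curve: CumulativeCurve, path: str | Path, title: str = "") -> None:
    """Fraction of simulations profitable at or below each volume; 95% marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.step(curve.grid, curve.cum_fraction, where="post", color="black")
    ax.axhline(0.95, color="0.6", linestyle="--", label="95% of simulations")
    ax.set_xlabel("administrations")
    ax.set_ylabel("fraction with positive ROI")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(result: TornadoResult, path: str | Path, title: str = "", top: int = 12) -> None:
    """Horizontal bars from outcome-at-low to outcome-at-high, widest on top."""
    df = result.table[result.table["range"] > 0].head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    base = result.outcome_at_means
    for i, row in enumerate(df.itertuples()):
        lo = min(row.outcome_at_low, row.outcome_at_high)
        hi = max(row.outcome_at_low, row.outcome_at_high)
        ax.barh(i, hi - lo, left=lo, color="0.4")
    ax.axvline(base, color="black", linestyle="-", linewidth=1)
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["name"])
    ax.set_xlabel(result.outcome_name)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
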