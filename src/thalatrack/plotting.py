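"""Plots: percentile sweep curves and the three-panel consensus figure."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .consensus import ConsensusCurve
from .metrics import SweepCurve

__all__ = ["plot_sweep", "plot_consensus_panels"]


def plot_sweep(curve: SweepCurve, path: str | Path, ylabel: str | None = None):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.percentiles, curve.values, marker="o", ms=2.5, lw=1)
    ax.set_xlabel("connectivity threshold (percentile)")
    ax.set_ylabel(ylabel or curve.metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_consensus_panels(curve: ConsensusCurve, path: str | Path, title: str = ""):
    """Inter-subject overlap, atlas overlap, and their product with the
    optimum marked — the threshold-optimisation summary figure."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    panels = (
        (curve.intersubject_median, "inter-subject overlap (median Dice)"),
        (curve.atlas_median, "atlas overlap (median Dice)"),
        (curve.product, "consensus product"),
    )
    for ax, (values, label) in zip(axes, panels):
        ax.plot(curve.percentiles, values, lw=1.2)
        ax.set_xlabel("threshold percentile")
        ax.set_ylabel(label)
    axes[2].axvline(curve.optimum, color="crimson", ls="--", lw=1,
                    label=f"optimum = {curve.optimum:.0f}")
    axes[2].legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
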