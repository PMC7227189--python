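"""Figure analogues: carbon trajectories, composition stacks, BA histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scenario_pipeline import ScenarioResult

__all__ = [
    "plot_carbon_trajectories",
    "plot_composition",
    "plot_ba_histogram",
]


def plot_carbon_trajectories(
    result: ScenarioResult,
    disturbance_level: str = "1",
    ax=None,
):
    """Mean total-carbon trajectories per (scenario, dClim level), with
    95% intervals across replicates, at one disturbance level."""
    tc = result.total_carbon()
    tc = tc[tc["disturbance_level"] == disturbance_level]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for (scenario, dclim), grp in tc.groupby(["scenario", "dclim_level"]):
        stats = grp.groupby("year")["total_C_Mg"].agg(["mean", "std", "count"])
        half = 1.96 * stats["std"] / np.sqrt(stats["count"].clip(lower=1))
        style = "-" if scenario == "warming" else "--"
        line = ax.plot(stats.index, stats["mean"], style, label=f"{scenario}, dClim {dclim}")
        ax.fill_between(
            stats.index,
            stats["mean"] - half.fillna(0),
            stats["mean"] + half.fillna(0),
            alpha=0.15,
            color=line[0].get_color(),
        )
    ax.set_xlabel("year")
    ax.set_ylabel("total aboveground carbon (Mg)")
    ax.legend(fontsize=8)
    return ax


def plot_composition(
    result: ScenarioResult,
    scenario: str = "warming",
    dclim_level: str = "1.0",
    disturbance_level: str = "1",
    ax=None,
):
    """Stacked species basal-area proportions over time for one cell."""
    comp = result.composition()
    comp = comp[
        (comp["scenario"] == scenario)
        & (comp["dclim_level"] == dclim_level)
        & (comp["disturbance_level"] == disturbance_level)
    ]
    mean = comp.groupby(["year", "species"], as_index=False)["proportion"].mean()
    pivot = mean.pivot(index="year", columns="species", values="proportion").fillna(0.0)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    ax.stackplot(pivot.index, pivot.T.to_numpy(), labels=list(pivot.columns))
    ax.set_xlabel("year")
    ax.set_ylabel("basal area proportion")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, ncol=2)
    ax.set_title(f"{scenario}, dClim {dclim_level}, disturbance {disturbance_level}x")
    return ax


def plot_ba_histogram(inventories: dict[str, "Inventory"], bins=None, ax=None):
    """Plot-level live basal-area distributions for labelled inventories
    (e.g. initial conditions vs several end-of-horizon states)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    if bins is None:
        bins = np.linspace(0, 120, 25)
    for label, inv in inventories.items():
        values = [p.live_basal_area for p in inv.plots]
        ax.hist(values, bins=bins, alpha=0.5, label=label)
    ax.set_xlabel("plot live basal area (m$^2$/ha)")
    ax.set_ylabel("plots")
    ax.legend(fontsize=8)
    return ax
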