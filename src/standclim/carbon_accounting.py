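"""Aboveground carbon and species-composition accounting.

Tree carbon uses a deliberately simple allometric chain declared in the
species table: stem volume from a form-factor cylinder, whole-tree
aboveground biomass via wood density and a crown expansion factor, and
carbon as half the dry biomass.  The aboveground pool is live plus
standing-dead trees; forest totals multiply plot-level per-hectare values
by the plot expansion factor (hectares represented per plot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import Inventory, Plot, SpeciesParams

__all__ = [
    "CARBON_FRACTION",
    "CarbonReport",
    "tree_carbon",
    "plot_carbon",
    "forest_totals",
]

#: Carbon fraction of dry biomass.
CARBON_FRACTION = 0.5


def tree_carbon(dbh: float, height: float, species_params: SpeciesParams) -> float:
    """Aboveground carbon (kg C) of a single tree.

    ``stem volume = form_factor * (pi/4) * (dbh/100)^2 * height`` (m^3),
    ``biomass = volume * wood_density * crown_factor`` (kg),
    ``carbon = 0.5 * biomass``.
    """
    if dbh < 0 or height < 0:
        raise ValueError("DBH and height must be >= 0")
    volume = species_params.form_factor * (math.pi / 4.0) * (dbh / 100.0) ** 2 * height
    biomass = volume * species_params.wood_density * species_params.crown_factor
    return CARBON_FRACTION * biomass


def plot_carbon(
    plot: Plot,
    species_pool: dict[str, SpeciesParams],
    pool: str = "both",
) -> float:
    """Aboveground carbon (Mg C/ha) of a plot's live and/or snag trees.

    ``pool`` is one of ``"live"``, ``"snag"``, ``"both"``; ``both`` is
    exactly the sum of the other two.
    """
    if pool not in ("live", "snag", "both"):
        raise ValueError(f"unknown carbon pool {pool!r}")
    total = 0.0
    if pool in ("live", "both"):
        for c in plot.cohorts:
            total += c.density * tree_carbon(c.dbh, c.height, species_pool[c.species])
    if pool in ("snag", "both"):
        for s in plot.snags:
            total += s.density * tree_carbon(s.dbh, s.height, species_pool[s.species])
    return total / 1000.0  # kg/ha -> Mg/ha


@dataclass
class CarbonReport:
    """Forest-level carbon and composition at one point in time.

    ``forest_live_carbon`` / ``forest_snag_carbon`` are totals in Mg,
    expanded by plot expansion factors; ``species_ba`` maps species code
    to total basal area (m^2) and ``species_proportions`` normalizes it
    (summing to 1 whenever any live basal area exists).
    """

    year: int
    plot_live_carbon: dict[str, float]  # Mg/ha per plot
    plot_snag_carbon: dict[str, float]
    forest_live_carbon: float  # Mg
    forest_snag_carbon: float  # Mg
    species_ba: dict[str, float]  # m^2
    species_proportions: dict[str, float] = field(default_factory=dict)

    @property
    def forest_total_carbon(self) -> float:
        return self.forest_live_carbon + self.forest_snag_carbon


def forest_totals(inventory: Inventory, year: int) -> CarbonReport:
    """Expand plot-level carbon and species basal area to forest totals.

    Forest carbon is the sum over plots of per-hectare carbon times the
    expansion factor; species basal-area totals likewise.  The result is
    invariant to plot order and to splitting a plot into two identical
    half-expansion plots.
    """
    pool = inventory.species_pool
    plot_live: dict[str, float] = {}
    plot_snag: dict[str, float] = {}
    live_total = 0.0
    snag_total = 0.0
    species_ba: dict[str, float] = {code: 0.0 for code in sorted(pool)}
    for plot in inventory.plots:
        live = plot_carbon(plot, pool, "live")
        snag = plot_carbon(plot, pool, "snag")
        plot_live[plot.id] = live
        plot_snag[plot.id] = snag
        live_total += live * plot.expansion_factor
        snag_total += snag * plot.expansion_factor
        for cohort in plot.cohorts:
            species_ba[cohort.species] += cohort.basal_area * plot.expansion_factor
    total_ba = sum(species_ba.values())
    proportions = (
        {code: ba / total_ba for code, ba in species_ba.items()} if total_ba > 0 else {}
    )
    return CarbonReport(
        year=year,
        plot_live_carbon=plot_live,
        plot_snag_carbon=plot_snag,
        forest_live_carbon=live_total,
        forest_snag_carbon=snag_total,
        species_ba=species_ba,
        species_proportions=proportions,
    )
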