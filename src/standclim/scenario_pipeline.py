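"""The per-cycle update loop and the factorial sensitivity experiment.

Each 10-year cycle applies, in a fixed order that configuration cannot
change: (1) advance climate; (2) dClim cohort mortality (skipped when the
rule is off); (3) viability-envelope mortality; (4) stochastic
disturbance events; (5) diameter/height growth; (6) density-dependent
mortality against the viability-modified maximum SDI; (7) planting when
stocking is below threshold; (8) snag decay.  Regeneration therefore sees
post-mortality stocking.

Replicates differ only through the disturbance draws.  Under common
random numbers (the default), the draw stream for a given (replicate,
plot, cycle) is identical in every factorial cell, so comparisons across
dClim or disturbance levels are paired and monotone effects are visible
without large replicate counts.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carbon_accounting import forest_totals
from .climate_mortality import (
    DClimConfig,
    ViabilityModel,
    dclim_triggered,
    envelope_survival_multiplier,
    effective_max_sdi,
)
from .core import ClimateGradient, ClimateTrajectory, Inventory, Plot, SnagRecord
from .disturbance import (
    DISTURBANCE_CLASSES,
    DisturbanceRegime,
    apply_event,
    sample_cycle_events,
    scale_regime,
)
from .io_formats import RESULT_COLUMNS, RunConfig, dclim_label, disturbance_label
from .stand_dynamics import (
    RegenerationConfig,
    age_snags,
    density_mortality,
    grow_cohorts,
    regenerate,
    stand_sdi,
    stocking_percent,
)
from .synthetic_data import DEFAULT_GRADIENT, make_climate_scenario

__all__ = [
    "ScenarioCell",
    "ScenarioResult",
    "run_cycle",
    "run_simulation",
    "run_factorial",
    "summarize_ratios",
    "MORTALITY_CAUSES",
]

MORTALITY_CAUSES = ("dclim", "envelope", "density") + DISTURBANCE_CLASSES

#: Cohorts thinner than this (TPH) are culled to the snag pool to keep the
#: cohort list from accumulating numerically dead entries.
_MIN_COHORT_DENSITY = 0.01


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the factorial design."""

    scenario: str  # "none" | "warming"
    dclim_multiplier: float | None  # None = rule off
    disturbance_multiplier: float

    @property
    def labels(self) -> tuple[str, str, str]:
        return (
            self.scenario,
            dclim_label(self.dclim_multiplier),
            disturbance_label(self.disturbance_multiplier),
        )


def _cycle_rng(
    master_seed: int,
    replicate: int,
    cycle: int,
    plot_index: int,
    cell_tag: int = 0,
) -> np.random.Generator:
    """Deterministic per-(replicate, cycle, plot) generator.

    ``cell_tag`` is 0 under common random numbers, making the disturbance
    stream identical across factorial cells that share a replicate index;
    independent-run designs pass a distinct tag per cell.
    """
    ss = np.random.SeedSequence((master_seed, cell_tag, replicate, cycle, plot_index))
    return np.random.Generator(np.random.PCG64(ss))


def run_cycle(
    plot: Plot,
    climate_now: dict[str, float],
    regime: DisturbanceRegime,
    dclim_config: DClimConfig,
    viability_model: ViabilityModel,
    regen_config: RegenerationConfig,
    rng: np.random.Generator,
    year: int,
    cycle_years: int = 10,
    snag_retention: float = 0.7,
    sdi_floor: float = 0.2,
    dclim_require_all: bool = False,
    attribution: dict[str, float] | None = None,
) -> Plot:
    """Advance one plot through one cycle, in place.

    ``attribution`` (cause -> basal area killed, m^2/ha) is accumulated
    when supplied.  ``climate_now`` is the climate at the end of the
    cycle being simulated.
    """
    species_pool = viability_model.species_pool

    def attribute(cause: str, ba: float) -> None:
        if attribution is not None and ba > 0:
            attribution[cause] = attribution.get(cause, 0.0) + ba

    # (2) dClim rule: sudden whole-cohort die-off.
    if dclim_config.enabled:
        survivors = []
        for cohort in plot.cohorts:
            if dclim_triggered(cohort, climate_now, dclim_config, dclim_require_all):
                plot.snags.append(
                    SnagRecord(cohort.species, cohort.density, cohort.dbh, cohort.height, year)
                )
                attribute("dclim", cohort.basal_area)
            else:
                survivors.append(cohort)
        plot.cohorts = survivors

    # (3) envelope mortality: linear density ramp below the threshold.
    survivors = []
    for cohort in plot.cohorts:
        score = viability_model.score(cohort.species, climate_now)
        mult = envelope_survival_multiplier(score, viability_model.threshold)
        killed = cohort.density * (1.0 - mult)
        remaining = cohort.density - killed
        if remaining < _MIN_COHORT_DENSITY:
            killed = cohort.density
            remaining = 0.0
        if killed > 0:
            plot.snags.append(
                SnagRecord(cohort.species, killed, cohort.dbh, cohort.height, year)
            )
            attribute("envelope", killed * np.pi * (cohort.dbh / 200.0) ** 2)
        cohort.density = remaining
        if remaining > 0:
            survivors.append(cohort)
    plot.cohorts = survivors

    # (4) disturbance events, fixed class order harvest -> fire -> stress.
    events = sample_cycle_events(regime, plot, rng, year)
    for event in events:
        ba_before = plot.live_basal_area
        apply_event(plot, event)
        attribute(event.disturbance_class, ba_before - plot.live_basal_area)
    if events:
        plot.cohorts = [c for c in plot.cohorts if c.density >= _MIN_COHORT_DENSITY]

    # (5) growth under the competition level set by current capacity.
    eff_max = effective_max_sdi(plot, climate_now, viability_model, sdi_floor)
    sdi_ratio = stand_sdi(plot) / eff_max if eff_max > 0 else 0.0
    grow_cohorts(plot, species_pool, sdi_ratio, cycle_years)

    # (6) self-thinning against the capacity (recomputed: growth moved BA).
    eff_max = effective_max_sdi(plot, climate_now, viability_model, sdi_floor)
    ba_before = plot.live_basal_area
    density_mortality(plot, eff_max, year)
    attribute("density", ba_before - plot.live_basal_area)

    # (7) plant climatically suited species when understocked.
    if stocking_percent(plot, eff_max) < regen_config.stocking_threshold:
        regenerate(plot, climate_now, viability_model, regen_config, year)

    # (8) snag decay.
    age_snags(plot, snag_retention)
    return plot


def _initialize_establishment(inventory: Inventory, trajectory: ClimateTrajectory) -> None:
    """Give cohorts without a recorded establishment climate their plot's
    normals as the dClim baseline."""
    for plot in inventory.plots:
        normal = trajectory.normal(plot.id)
        for cohort in plot.cohorts:
            if cohort.establishment_climate is None:
                cohort.establishment_climate = dict(normal)


def run_simulation(
    inventory: Inventory,
    trajectory: ClimateTrajectory,
    cell: ScenarioCell,
    config: RunConfig,
    regime: DisturbanceRegime,
    replicate: int,
    gradient: ClimateGradient = DEFAULT_GRADIENT,
) -> tuple[list[dict], list[dict]]:
    """Run one factorial cell for one replicate over the full horizon.

    Returns (result rows, attribution rows) in the long formats of
    ``results.csv`` and ``mortality_attribution.csv``.  Carbon rows carry
    species ``ALL``; per-species basal area rows carry the species code.
    """
    origin = inventory.origin_year
    if not trajectory.covers(origin, config.horizon_years):
        raise ValueError(
            f"trajectory years {trajectory.years.min()}..{trajectory.years.max()} "
            f"do not cover {origin}..{origin + config.horizon_years}"
        )
    scenario, dclim_lab, dist_lab = cell.labels
    work = inventory.copy()
    _initialize_establishment(work, trajectory)
    scaled = scale_regime(regime, cell.disturbance_multiplier)
    dclim_config = DClimConfig(gradients=gradient, multiplier=cell.dclim_multiplier)
    viability_model = ViabilityModel(work.species_pool)
    regen_config = RegenerationConfig(
        stocking_threshold=config.stocking_threshold,
        planting_density=config.planting_density,
        max_species=config.max_regen_species,
    )
    cell_tag = (
        0
        if config.common_random_numbers
        else zlib.crc32("|".join(cell.labels).encode()) % (2**31)
    )

    year_index = {int(y): i for i, y in enumerate(trajectory.years)}
    metrics = trajectory.metrics

    rows: list[dict] = []
    attr_rows: list[dict] = []

    def emit(report) -> None:
        base = {
            "scenario": scenario,
            "dclim_level": dclim_lab,
            "disturbance_level": dist_lab,
            "replicate": replicate,
            "year": report.year,
        }
        rows.append(
            base | {"variable": "live_C_Mg", "species": "ALL", "value": report.forest_live_carbon}
        )
        rows.append(
            base | {"variable": "snag_C_Mg", "species": "ALL", "value": report.forest_snag_carbon}
        )
        for code in sorted(report.species_ba):
            rows.append(
                base | {"variable": "ba_m2", "species": code, "value": report.species_ba[code]}
            )

    emit(forest_totals(work, origin))

    for cycle in range(1, config.n_cycles + 1):
        year = origin + cycle * config.cycle_years
        yi = year_index[year]
        attribution: dict[str, float] = {}
        for plot_index, plot in enumerate(work.plots):
            row = trajectory.values[plot.id][yi]
            climate_now = dict(zip(metrics, row.tolist()))
            expanded: dict[str, float] = {}
            run_cycle(
                plot,
                climate_now,
                scaled,
                dclim_config,
                viability_model,
                regen_config,
                _cycle_rng(config.master_seed, replicate, cycle, plot_index, cell_tag),
                year,
                config.cycle_years,
                config.snag_retention,
                config.sdi_floor,
                config.dclim_require_all,
                expanded,
            )
            for cause, ba in expanded.items():
                attribution[cause] = attribution.get(cause, 0.0) + ba * plot.expansion_factor
        emit(forest_totals(work, year))
        for cause in MORTALITY_CAUSES:
            attr_rows.append(
                {
                    "scenario": scenario,
                    "dclim_level": dclim_lab,
                    "disturbance_level": dist_lab,
                    "replicate": replicate,
                    "year": year,
                    "cause": cause,
                    "ba_killed_m2": attribution.get(cause, 0.0),
                }
            )
    return rows, attr_rows


@dataclass
class ScenarioResult:
    """Long-format projection results plus per-cycle mortality attribution.

    ``table`` has the ``results.csv`` columns; ``attribution`` records
    basal area killed (m^2, expanded) per cause per cycle per cell.
    """

    table: pd.DataFrame
    attribution: pd.DataFrame
    config: RunConfig
    origin_year: int = 2016

    @property
    def end_year(self) -> int:
        return self.origin_year + self.config.horizon_years

    def total_carbon(self) -> pd.DataFrame:
        """Total (live + snag) forest carbon (Mg) per cell, replicate, year."""
        carbon = self.table[self.table["variable"].isin(["live_C_Mg", "snag_C_Mg"])]
        keys = ["scenario", "dclim_level", "disturbance_level", "replicate", "year"]
        return carbon.groupby(keys, as_index=False)["value"].sum().rename(
            columns={"value": "total_C_Mg"}
        )

    def end_carbon(self) -> pd.DataFrame:
        tc = self.total_carbon()
        return tc[tc["year"] == self.end_year].reset_index(drop=True)

    def composition(self) -> pd.DataFrame:
        """Species basal-area proportions per cell, replicate, year."""
        ba = self.table[self.table["variable"] == "ba_m2"].copy()
        keys = ["scenario", "dclim_level", "disturbance_level", "replicate", "year"]
        totals = ba.groupby(keys)["value"].transform("sum")
        ba["proportion"] = np.where(totals > 0, ba["value"] / totals, 0.0)
        return ba

    def summarize_ratios(
        self, reference: tuple[str, str] = ("1.0", "1")
    ) -> pd.DataFrame:
        return summarize_ratios(self, reference)


def run_factorial(
    inventory: Inventory,
    trajectories: dict[str, ClimateTrajectory],
    regime: DisturbanceRegime,
    config: RunConfig,
    gradient: ClimateGradient = DEFAULT_GRADIENT,
) -> ScenarioResult:
    """Execute the full factorial: climate x dClim x disturbance x replicate.

    ``trajectories`` maps each scenario name in the config to its climate
    trajectory.  With common random numbers (default) cells sharing a
    replicate index reuse the same disturbance draw stream.
    """
    missing = set(config.climate_scenarios) - set(trajectories)
    if missing:
        raise ValueError(f"no trajectory supplied for scenario(s) {sorted(missing)}")
    all_rows: list[dict] = []
    all_attr: list[dict] = []
    cells = [
        ScenarioCell(s, d, m)
        for s, d, m in itertools.product(
            config.climate_scenarios, config.dclim_levels, config.disturbance_levels
        )
    ]
    for cell in cells:
        trajectory = trajectories[cell.scenario]
        for replicate in range(config.n_replicates):
            rows, attr = run_simulation(
                inventory, trajectory, cell, config, regime, replicate, gradient
            )
            all_rows.extend(rows)
            all_attr.extend(attr)
    table = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    attribution = pd.DataFrame(all_attr)
    return ScenarioResult(table, attribution, config, inventory.origin_year)


def summarize_ratios(
    result: ScenarioResult, reference: tuple[str, str] = ("1.0", "1")
) -> pd.DataFrame:
    """End-of-horizon carbon of every cell relative to the reference cell.

    Within each climate scenario, each (dClim level, disturbance level)
    cell's replicate-mean end-year total carbon is divided by that of the
    reference cell (default: dClim 1.0, base disturbance).  The reference
    row has ratio exactly 1.
    """
    ref_dclim, ref_dist = reference
    end = result.end_carbon()
    means = end.groupby(
        ["scenario", "dclim_level", "disturbance_level"], as_index=False
    )["total_C_Mg"].mean()
    out = []
    for scenario, grp in means.groupby("scenario"):
        ref = grp[
            (grp["dclim_level"] == ref_dclim) & (grp["disturbance_level"] == ref_dist)
        ]
        if ref.empty:
            raise ValueError(
                f"reference cell (dClim {ref_dclim}, disturbance {ref_dist}) "
                f"not present in scenario {scenario!r}"
            )
        ref_mean = float(ref["total_C_Mg"].iloc[0])
        grp = grp.copy()
        grp["ratio"] = grp["total_C_Mg"] / ref_mean if ref_mean != 0 else 0.0
        out.append(grp)
    return pd.concat(out, ignore_index=True)
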