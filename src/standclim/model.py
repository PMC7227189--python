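"""Model/results interface for climate-sensitive forest projection.

:class:`ForestProjectionModel` bundles the data a projection needs — an
inventory, a repeat-measurement table, per-plot climate normals and a run
configuration.  ``fit()`` estimates the empirical disturbance regime
(per-class 10-year probabilities with Clopper-Pearson confidence
intervals, plus magnitude ECDFs) and returns a
:class:`ForestProjectionResults` from which simulation, the factorial
sensitivity experiment, summaries and plots all hang.

>>> model = ForestProjectionModel.from_synthetic(n_plots=50, seed=7)
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
>>> sim = res.simulate(scenario="warming", dclim=1.0)
>>> sim.total_carbon().head()     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core import ClimateGradient, ClimateTrajectory, Inventory
from .disturbance import DISTURBANCE_CLASSES, DisturbanceRegime, estimate_regime
from .io_formats import (
    RemeasurementTable,
    RunConfig,
    read_climate,
    read_inventory,
    read_remeasurements,
)
from .scenario_pipeline import (
    ScenarioCell,
    ScenarioResult,
    run_factorial,
    run_simulation,
)
from .synthetic_data import (
    DEFAULT_GRADIENT,
    DEFAULT_MAGNITUDES,
    make_climate_scenario,
    make_landscape,
    make_remeasurement_data,
)

__all__ = ["ForestProjectionModel", "ForestProjectionResults"]

#: Ochoco-NF-style default truth for synthetic remeasurement tables
#: (harvest, fire, stress 10-year probabilities).
_DEFAULT_TRUE_PROBS = {"harvest": 0.132, "fire": 0.093, "stress": 0.335}


class ForestProjectionModel:
    """A 100-year, climate-sensitive forest projection experiment.

    Parameters
    ----------
    inventory : Inventory
        Plots, cohorts and the species pool.
    remeasurements : RemeasurementTable
        Repeat-measurement records the disturbance regime is estimated from.
    normals : dict
        Per-plot 1960-1990 climate-normal vectors (plot id -> array in
        metric order).
    config : RunConfig, optional
        Experiment settings; defaults reproduce the standard design
        (2 scenarios x 4 dClim levels x 4 disturbance levels x 10
        replicates over 2016-2116).
    gradient : ClimateGradient, optional
        Climate-vs-elevation gradient used by the dClim rule.
    """

    def __init__(
        self,
        inventory: Inventory,
        remeasurements: RemeasurementTable,
        normals: dict[str, np.ndarray],
        config: RunConfig | None = None,
        gradient: ClimateGradient = DEFAULT_GRADIENT,
        metrics: tuple[str, ...] = ("mat", "map"),
    ) -> None:
        self.inventory = inventory
        self.remeasurements = remeasurements
        self.normals = {pid: np.asarray(v, dtype=float) for pid, v in normals.items()}
        self.config = config or RunConfig()
        self.gradient = gradient
        self.metrics = tuple(metrics)
        missing = {p.id for p in inventory.plots} - set(self.normals)
        if missing:
            raise ValueError(f"plots without climate normals: {sorted(missing)[:10]}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        plots_path,
        trees_path,
        species_path,
        remeasure_path,
        climate_path,
        config: RunConfig | None = None,
        gradient: ClimateGradient = DEFAULT_GRADIENT,
    ) -> "ForestProjectionModel":
        """Build the model from the documented CSV schemas."""
        inventory = read_inventory(plots_path, trees_path, species_path)
        remeasurements = read_remeasurements(remeasure_path)
        trajectory = read_climate(climate_path)
        model = cls(
            inventory,
            remeasurements,
            trajectory.normals,
            config,
            gradient,
            tuple(trajectory.metrics),
        )
        return model

    @classmethod
    def from_synthetic(
        cls,
        n_plots: int = 100,
        n_species: int = 8,
        seed: int = 0,
        n_remeasure_plots: int = 343,
        true_probs: dict[str, float] | None = None,
        reserved_fraction: float = 0.34,
        config: RunConfig | None = None,
        gradient: ClimateGradient = DEFAULT_GRADIENT,
    ) -> "ForestProjectionModel":
        """Build the model from the synthetic-data generators.

        The landscape, species pool and remeasurement table are generated
        with the given seed; remeasurement truth defaults to the
        Ochoco-style regime (harvest 0.132, fire 0.093, stress 0.335).
        """
        inventory, normals = make_landscape(
            n_plots,
            gradient=gradient,
            seed=seed,
            n_species=n_species,
            reserved_fraction=reserved_fraction,
        )
        remeasurements = make_remeasurement_data(
            true_probs or dict(_DEFAULT_TRUE_PROBS),
            DEFAULT_MAGNITUDES,
            n_remeasure_plots,
            seed + 1,
        )
        return cls(inventory, remeasurements, normals, config, gradient)

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "ForestProjectionResults":
        """Estimate the disturbance regime and return a results object."""
        regime = estimate_regime(self.remeasurements)
        return ForestProjectionResults(self, regime)

    def trajectories(self) -> dict[str, ClimateTrajectory]:
        """Climate trajectories for every scenario in the configuration."""
        out: dict[str, ClimateTrajectory] = {}
        cfg = self.config
        for scenario in cfg.climate_scenarios:
            shape = "constant" if scenario == "none" else cfg.warming_shape
            out[scenario] = make_climate_scenario(
                self.normals,
                cfg.warming_delta,
                shape,
                metrics=self.metrics,
                origin_year=self.inventory.origin_year,
                horizon_years=cfg.horizon_years,
                cycle_years=cfg.cycle_years,
            )
        return out


class ForestProjectionResults:
    """Fitted disturbance regime plus the simulation entry points.

    Attributes
    ----------
    regime : DisturbanceRegime
        The estimated regime (per-class probability, counts, magnitude
        ECDF).
    params : pandas.Series
        The per-class 10-year disturbance probabilities.
    """

    def __init__(self, model: ForestProjectionModel, regime: DisturbanceRegime) -> None:
        self.model = model
        self.regime = regime
        self.params = pd.Series(
            {cls: regime.probabilities[cls] for cls in DISTURBANCE_CLASSES},
            name="probability",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Clopper-Pearson (exact binomial) CI per disturbance class."""
        rows = {}
        for cls in DISTURBANCE_CLASSES:
            lo, hi = proportion_confint(
                self.regime.n_disturbed[cls],
                self.regime.n_remeasured,
                alpha=alpha,
                method="beta",
            )
            rows[cls] = (lo, hi)
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def summary(self) -> str:
        """Human-readable summary of the fitted disturbance regime."""
        ci = self.conf_int()
        lines = [
            "Empirical 10-year disturbance regime",
            "=" * 60,
            f"remeasured plots: {self.regime.n_remeasured}",
            "",
            f"{'class':<10}{'n':>6}{'p':>9}{'95% CI':>22}{'median m':>12}",
            "-" * 60,
        ]
        for cls in DISTURBANCE_CLASSES:
            mags = self.regime.magnitudes[cls]
            med = float(np.median(mags)) if self.regime.n_disturbed[cls] else 0.0
            lines.append(
                f"{cls:<10}{self.regime.n_disturbed[cls]:>6}"
                f"{self.params[cls]:>9.3f}"
                f"{'[%.3f, %.3f]' % (ci.loc[cls, 'lower'], ci.loc[cls, 'upper']):>22}"
                f"{med:>12.3f}"
            )
        lines.append("-" * 60)
        lines.append(
            "p = plots disturbed / plots remeasured; m = proportion of "
            "basal area killed"
        )
        return "\n".join(lines)

    # -- simulation ---------------------------------------------------------

    def simulate(
        self,
        scenario: str = "warming",
        dclim: float | None = 1.0,
        disturbance: float = 1.0,
        n_replicates: int | None = None,
        seed: int | None = None,
    ) -> ScenarioResult:
        """Run a single factorial cell for ``n_replicates`` replicates."""
        model = self.model
        cfg = model.config
        if seed is not None or n_replicates is not None:
            cfg = _dc_replace(
                cfg,
                master_seed=cfg.master_seed if seed is None else seed,
                n_replicates=cfg.n_replicates if n_replicates is None else n_replicates,
            )
        trajectory = model.trajectories()[scenario] if scenario in cfg.climate_scenarios else None
        if trajectory is None:
            # scenario not in configured list: still allow it directly
            from .synthetic_data import make_climate_scenario

            shape = "constant" if scenario == "none" else cfg.warming_shape
            trajectory = make_climate_scenario(
                model.normals,
                cfg.warming_delta,
                shape,
                metrics=model.metrics,
                origin_year=model.inventory.origin_year,
                horizon_years=cfg.horizon_years,
                cycle_years=cfg.cycle_years,
            )
        cell = ScenarioCell(scenario, dclim, disturbance)
        rows: list[dict] = []
        attr: list[dict] = []
        for rep in range(cfg.n_replicates):
            r, a = run_simulation(
                model.inventory, trajectory, cell, cfg, self.regime, rep, model.gradient
            )
            rows.extend(r)
            attr.extend(a)
        from .io_formats import RESULT_COLUMNS

        return ScenarioResult(
            pd.DataFrame(rows, columns=RESULT_COLUMNS),
            pd.DataFrame(attr),
            cfg,
            model.inventory.origin_year,
        )

    def run_factorial(self, seed: int | None = None) -> ScenarioResult:
        """Run the full configured factorial design."""
        model = self.model
        cfg = model.config if seed is None else _dc_replace(model.config, master_seed=seed)
        return run_factorial(
            model.inventory, model.trajectories(), self.regime, cfg, model.gradient
        )

    # -- plotting -----------------------------------------------------------

    def plot_carbon_trajectories(self, result: ScenarioResult, **kwargs):
        from .plotting import plot_carbon_trajectories

        return plot_carbon_trajectories(result, **kwargs)

    def plot_composition(self, result: ScenarioResult, **kwargs):
        from .plotting import plot_composition

        return plot_composition(result, **kwargs)
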