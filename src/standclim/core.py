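"""Core domain types shared across the package.

Everything a simulation touches is one of a handful of plain dataclasses:
a :class:`SpeciesParams` record per species, :class:`TreeCohort` records
grouped into a :class:`Plot`, and climate described by a
:class:`ClimateGradient` (how metrics vary with elevation) and a
:class:`ClimateTrajectory` (per-plot metric time series plus 1960-1990
normals).  Units are fixed at the interface: DBH in cm, height in m,
density in trees per hectare (TPH), elevation in m, area in ha, carbon in
Mg, temperature in degrees C, precipitation in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BREAST_HEIGHT_M",
    "REINEKE_EXPONENT",
    "REINEKE_REFERENCE_DBH_CM",
    "SpeciesParams",
    "TreeCohort",
    "SnagRecord",
    "Plot",
    "Inventory",
    "ClimateGradient",
    "ClimateTrajectory",
]

#: Breast height (m); the floor for any tree height and the seedling height.
BREAST_HEIGHT_M = 1.37

#: Reineke stand-density-index exponent and reference diameter (cm).
REINEKE_EXPONENT = 1.605
REINEKE_REFERENCE_DBH_CM = 25.4


@dataclass(frozen=True)
class SpeciesParams:
    """Growth, allometry and climatic-niche parameters for one species.

    The climatic niche is a separable Gaussian per metric: ``optimum`` and
    ``breadth`` map metric name -> value (same units as the metric).  The
    viability score of a climate is the product over metrics of
    ``exp(-0.5 * ((x - optimum) / breadth) ** 2)``.

    Parameters
    ----------
    code : str
        Short species code (e.g. ``"SP01"`` or an FIA-style symbol).
    optimum, breadth : dict
        Niche optimum and breadth per climate metric; breadths must be > 0.
    max_dbh : float
        Asymptotic diameter (cm); the annual increment tapers to zero here.
    max_increment : float
        Open-grown annual diameter increment (cm/yr) at DBH 0.
    height_k : float
        Shape parameter of the saturating height-diameter curve (1/cm).
    height_cap : float
        Hard ceiling on tree height (m); must exceed breast height.
    wood_density : float
        Dry wood density (kg/m^3).
    crown_factor : float
        Multiplier (>= 1) expanding stem biomass to whole-tree aboveground
        biomass (branches + foliage).
    base_max_sdi : float
        Maximum stand density index (TPH at the 25.4 cm reference diameter)
        the species supports under fully suitable climate.
    form_factor : float
        Stem form factor relating the DBH-height cylinder to stem volume.
    """

    code: str
    optimum: dict[str, float]
    breadth: dict[str, float]
    max_dbh: float
    max_increment: float
    height_k: float
    height_cap: float
    wood_density: float
    crown_factor: float
    base_max_sdi: float
    form_factor: float = 0.42

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.breadth.values()):
            raise ValueError(f"species {self.code}: niche breadths must be > 0")
        if self.height_cap <= BREAST_HEIGHT_M:
            raise ValueError(
                f"species {self.code}: height cap must exceed {BREAST_HEIGHT_M} m"
            )
        if self.crown_factor < 1:
            raise ValueError(f"species {self.code}: crown factor must be >= 1")

    def height_at(self, dbh: float) -> float:
        """Height (m) from the saturating height-diameter curve, capped."""
        h = BREAST_HEIGHT_M + (self.height_cap - BREAST_HEIGHT_M) * (
            1.0 - math.exp(-self.height_k * dbh)
        )
        return min(h, self.height_cap)


@dataclass
class TreeCohort:
    """A group of identical trees on a plot.

    ``establishment_climate`` is the climate vector (metric -> value) at the
    time the cohort established; it is the memory against which the dClim
    elevation-window rule measures climate change.  ``None`` means
    "initialise from the plot's normals at simulation start".
    """

    species: str
    density: float  # TPH
    dbh: float  # cm
    height: float  # m
    establishment_year: int
    establishment_climate: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("cohort density must be >= 0")
        if self.dbh < 0:
            raise ValueError("cohort DBH must be >= 0")

    @property
    def basal_area(self) -> float:
        """Basal area (m^2/ha) of the cohort."""
        return self.density * math.pi * (self.dbh / 200.0) ** 2

    def copy(self) -> "TreeCohort":
        clim = None if self.establishment_climate is None else dict(self.establishment_climate)
        return TreeCohort(
            self.species, self.density, self.dbh, self.height,
            self.establishment_year, clim,
        )


@dataclass
class SnagRecord:
    """A standing-dead cohort: dimensions frozen at death, density decays."""

    species: str
    density: float
    dbh: float
    height: float
    death_year: int

    @property
    def basal_area(self) -> float:
        return self.density * math.pi * (self.dbh / 200.0) ** 2

    def copy(self) -> "SnagRecord":
        return replace(self)


@dataclass
class Plot:
    """An inventory plot: live cohorts, a snag pool, and sampling metadata.

    ``expansion_factor`` is the forest area (ha) the plot represents; plot
    per-hectare values times the expansion factor give forest totals.
    ``reserved`` plots are excluded from harvest.
    """

    id: str
    elevation: float
    reserved: bool
    expansion_factor: float
    cohorts: list[TreeCohort] = field(default_factory=list)
    snags: list[SnagRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expansion_factor <= 0:
            raise ValueError(f"plot {self.id}: expansion factor must be > 0")

    @property
    def live_basal_area(self) -> float:
        """Live basal area (m^2/ha)."""
        return sum(c.basal_area for c in self.cohorts)

    @property
    def snag_basal_area(self) -> float:
        return sum(s.basal_area for s in self.snags)

    def copy(self) -> "Plot":
        return Plot(
            self.id, self.elevation, self.reserved, self.expansion_factor,
            [c.copy() for c in self.cohorts],
            [s.copy() for s in self.snags],
        )


@dataclass
class Inventory:
    """A collection of plots plus the species pool they draw from."""

    plots: list[Plot]
    species_pool: dict[str, SpeciesParams]
    origin_year: int = 2016

    def __post_init__(self) -> None:
        ids = [p.id for p in self.plots]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot ids: {dup}")
        unknown = sorted(
            {c.species for p in self.plots for c in p.cohorts} - set(self.species_pool)
        )
        if unknown:
            raise ValueError(f"cohort species not in species pool: {unknown}")

    def copy(self) -> "Inventory":
        return Inventory(
            [p.copy() for p in self.plots], dict(self.species_pool), self.origin_year
        )


@dataclass(frozen=True)
class ClimateGradient:
    """Rates of change of climate metrics with elevation (units per m).

    By convention the temperature gradient is negative (cooler aloft); the
    default is the standard environmental lapse rate.
    """

    rates: dict[str, float]

    def __post_init__(self) -> None:
        for name, r in self.rates.items():
            if not math.isfinite(r):
                raise ValueError(f"gradient for {name} must be finite")

    @property
    def metrics(self) -> list[str]:
        return list(self.rates)


@dataclass
class ClimateTrajectory:
    """Per-plot climate-metric time series at cycle resolution, plus normals.

    ``values[plot_id]`` is an array of shape (n_years, n_metrics) aligned
    with ``years`` and ``metrics``; ``normals[plot_id]`` is the 1960-1990
    normal vector for the plot.
    """

    metrics: list[str]
    years: np.ndarray
    values: dict[str, np.ndarray]
    normals: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for pid, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.years), len(self.metrics)):
                raise ValueError(
                    f"plot {pid}: trajectory shape {arr.shape} does not match "
                    f"({len(self.years)}, {len(self.metrics)})"
                )
            self.values[pid] = arr

    def covers(self, origin_year: int, horizon_years: int) -> bool:
        return bool(
            self.years.min() <= origin_year
            and self.years.max() >= origin_year + horizon_years
        )

    def at(self, plot_id: str, year: int) -> dict[str, float]:
        """Climate vector for ``plot_id`` at calendar ``year`` (exact match)."""
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in trajectory (have {self.years.tolist()})")
        row = self.values[plot_id][idx[0]]
        return dict(zip(self.metrics, row.tolist()))

    def normal(self, plot_id: str) -> dict[str, float]:
        return dict(zip(self.metrics, np.asarray(self.normals[plot_id]).tolist()))
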