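"""Synthetic landscapes, species pools, climate and remeasurement tables.

The generators emulate the structure of a western-US National Forest
inventory: plots strung along an elevation gradient (climate derived from
elevation through a lapse-rate-style gradient), a pool of species with
unimodal climatic niches spread across that gradient, repeat-measurement
records drawn from known per-class disturbance probabilities and
magnitude distributions, and warming trajectories bounded by the RCP6.0
range (ensemble mean +2.2 degC, range 1.4-3.1 degC by 2100).

Every generator is reproducible: the same seed gives bit-identical output.
Mean annual temperature ("mat", degC) and mean annual precipitation
("map", mm) are the default climate metrics; temperature is the primary
niche axis, precipitation a broad secondary one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .climate_mortality import VIABILITY_THRESHOLD, viability
from .core import (
    ClimateGradient,
    ClimateTrajectory,
    Inventory,
    Plot,
    SpeciesParams,
    TreeCohort,
)

__all__ = [
    "DEFAULT_METRICS",
    "DEFAULT_GRADIENT",
    "DEFAULT_BASE_CLIMATE",
    "DEFAULT_WARMING_DELTA",
    "DEFAULT_MAGNITUDES",
    "MagnitudeDistribution",
    "SpeciesParams",
    "ClimateTrajectory",
    "ClimateGradient",
    "make_species_pool",
    "make_landscape",
    "make_remeasurement_data",
    "make_climate_scenario",
]

DEFAULT_METRICS = ("mat", "map")

#: Standard environmental lapse rate for temperature; a modest orographic
#: precipitation gradient.  Units per metre of elevation.
DEFAULT_GRADIENT = ClimateGradient({"mat": -0.0065, "map": 0.5})

#: Regional climate at the reference elevation (1000 m).
DEFAULT_BASE_CLIMATE = {"mat": 6.0, "map": 1000.0}
DEFAULT_REFERENCE_ELEVATION = 1000.0

#: Warming reaching the RCP6.0 ensemble-mean +2.2 degC (with a slight
#: precipitation increase) at the 100-year horizon.
DEFAULT_WARMING_DELTA = {"mat": 2.2, "map": 50.0}

_MAP_BREADTH_FRACTION = 0.35  # niche breadth in MAP as a fraction of its span
_MAT_BREADTH_FACTOR = 0.9  # niche breadth in MAT as a multiple of optimum spacing


def make_species_pool(
    n_species: int,
    climate_range: dict[str, tuple[float, float]],
    seed: int,
) -> dict[str, SpeciesParams]:
    """Generate a species pool whose niches tile a climate transect.

    ``climate_range`` maps each metric to its (lo, hi) range.  Optima for
    the primary metric ("mat") are evenly spaced across its range (with a
    small seeded jitter); optima for other metrics are paired linearly so
    that warm corresponds to the low-elevation end of each range (wetter
    aloft under the default gradient means warm pairs with dry).  Breadths
    are wide enough that every climate on the paired transect has at least
    one species with viability >= 0.5.

    Growth, allometry and density parameters are drawn from seeded uniform
    ranges typical of northwestern-US conifers.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    mat_lo, mat_hi = climate_range["mat"]
    spacing = (mat_hi - mat_lo) / (n_species - 1)
    mat_opts = np.linspace(mat_lo, mat_hi, n_species)
    mat_opts = mat_opts + rng.uniform(-0.08, 0.08, n_species) * spacing
    breadth_mat = _MAT_BREADTH_FACTOR * spacing

    other_metrics = [m for m in climate_range if m != "mat"]
    pool: dict[str, SpeciesParams] = {}
    for i in range(n_species):
        optimum = {"mat": float(mat_opts[i])}
        breadth = {"mat": float(breadth_mat)}
        frac = (mat_opts[i] - mat_lo) / (mat_hi - mat_lo)  # 0 = coldest
        for m in other_metrics:
            lo, hi = climate_range[m]
            # warm (high-mat) species sit at the low end of the other metric
            optimum[m] = float(hi - frac * (hi - lo))
            breadth[m] = float(max(_MAP_BREADTH_FRACTION * (hi - lo), 1e-6))
        code = f"SP{i + 1:02d}"
        pool[code] = SpeciesParams(
            code=code,
            optimum=optimum,
            breadth=breadth,
            max_dbh=float(rng.uniform(60.0, 120.0)),
            max_increment=float(rng.uniform(0.35, 0.7)),
            height_k=float(rng.uniform(0.025, 0.04)),
            height_cap=float(rng.uniform(30.0, 65.0)),
            wood_density=float(rng.uniform(350.0, 550.0)),
            crown_factor=float(rng.uniform(1.15, 1.3)),
            base_max_sdi=float(rng.uniform(650.0, 1100.0)),
        )
    return pool


def _normals_at(
    elevation: float,
    gradient: ClimateGradient,
    base_climate: dict[str, float],
    reference_elevation: float,
) -> dict[str, float]:
    return {
        m: base_climate[m] + gradient.rates[m] * (elevation - reference_elevation)
        for m in base_climate
    }


def make_landscape(
    n_plots: int,
    elevation_range: tuple[float, float] = (200.0, 2000.0),
    gradient: ClimateGradient = DEFAULT_GRADIENT,
    seed: int = 0,
    *,
    species_pool: dict[str, SpeciesParams] | None = None,
    n_species: int = 8,
    base_climate: dict[str, float] | None = None,
    reference_elevation: float = DEFAULT_REFERENCE_ELEVATION,
    reserved_fraction: float = 0.34,
    expansion_factor: float = 2400.0,
    origin_year: int = 2016,
    warm_headroom: float = 3.5,
    cold_headroom: float = 1.0,
) -> tuple[Inventory, dict[str, np.ndarray]]:
    """Generate an inventory along an elevation/climate gradient.

    Plot elevations are uniform in ``elevation_range``; each plot's
    1960-1990 normals are the regional base climate plus the gradient
    times the elevation offset from the reference.  Initial cohorts are
    drawn only from species viable (score >= 0.5) at the plot's normals,
    with stand density initialised between 45% and 80% of the species'
    supported maximum.  ``reserved_fraction`` of plots are flagged
    reserved (no harvest), mirroring wilderness set-asides.

    If no species pool is supplied, one is generated to span the
    landscape's temperature range with ``warm_headroom`` /
    ``cold_headroom`` (degC) beyond it, so warmer-adapted species are
    available to migrate upslope as climate changes.

    Returns
    -------
    (inventory, normals)
        The inventory and a dict mapping plot id to its normal climate
        vector (aligned with ``DEFAULT_METRICS`` order).
    """
    if n_plots < 1:
        raise ValueError("need at least 1 plot")
    lo, hi = elevation_range
    if not hi > lo:
        raise ValueError("elevation range must be nonempty")
    base_climate = dict(base_climate or DEFAULT_BASE_CLIMATE)
    rng = np.random.default_rng(seed)
    elevations = rng.uniform(lo, hi, n_plots)

    if species_pool is None:
        ends = [
            _normals_at(lo, gradient, base_climate, reference_elevation),
            _normals_at(hi, gradient, base_climate, reference_elevation),
        ]
        climate_range = {}
        for m in base_climate:
            vals = [e[m] for e in ends]
            climate_range[m] = (min(vals), max(vals))
        mat_lo, mat_hi = climate_range["mat"]
        climate_range["mat"] = (mat_lo - cold_headroom, mat_hi + warm_headroom)
        # extend the paired metrics proportionally along the transect
        for m in base_climate:
            if m == "mat":
                continue
            slope = gradient.rates[m] / gradient.rates["mat"]
            m_lo, m_hi = climate_range[m]
            climate_range[m] = (
                min(m_lo, m_lo + slope * warm_headroom, m_hi - slope * cold_headroom),
                max(m_hi, m_lo + slope * warm_headroom, m_hi - slope * cold_headroom),
            )
        species_pool = make_species_pool(n_species, climate_range, seed)

    n_reserved = int(round(reserved_fraction * n_plots))
    reserved_flags = np.zeros(n_plots, dtype=bool)
    reserved_flags[rng.choice(n_plots, size=n_reserved, replace=False)] = True

    metrics = list(base_climate)
    plots: list[Plot] = []
    normals: dict[str, np.ndarray] = {}
    codes = sorted(species_pool)
    for i in range(n_plots):
        pid = f"P{i + 1:04d}"
        climate = _normals_at(float(elevations[i]), gradient, base_climate, reference_elevation)
        normals[pid] = np.array([climate[m] for m in metrics])
        scores = np.array([viability(species_pool[c], climate) for c in codes])
        viable = [c for c, s in zip(codes, scores) if s >= VIABILITY_THRESHOLD]
        if not viable:  # guaranteed not to happen for pools built here
            raise RuntimeError(f"no viable species at plot {pid}")
        n_cohorts = int(rng.integers(2, 6))
        chosen = list(
            rng.choice(viable, size=min(n_cohorts, len(viable)), replace=False)
        )
        while len(chosen) < n_cohorts:
            chosen.append(str(rng.choice(viable)))
        dbhs = np.clip(rng.lognormal(math.log(25.0), 0.35, n_cohorts), 5.0, None)
        weights = rng.uniform(0.5, 1.5, n_cohorts)
        weights /= weights.sum()
        target_fraction = rng.uniform(0.45, 0.80)
        capacity = sum(
            w * species_pool[c].base_max_sdi * viability(species_pool[c], climate)
            for w, c in zip(weights, chosen)
        )
        target_sdi = target_fraction * capacity
        cohorts = []
        for c, dbh, w in zip(chosen, dbhs, weights):
            sp = species_pool[c]
            dbh = min(float(dbh), 0.8 * sp.max_dbh)
            density = w * target_sdi / (dbh / 25.4) ** 1.605
            cohorts.append(
                TreeCohort(
                    species=c,
                    density=float(density),
                    dbh=dbh,
                    height=sp.height_at(dbh),
                    establishment_year=origin_year,
                    establishment_climate=dict(climate),
                )
            )
        plots.append(
            Plot(
                id=pid,
                elevation=float(elevations[i]),
                reserved=bool(reserved_flags[i]),
                expansion_factor=expansion_factor,
                cohorts=cohorts,
            )
        )
    inventory = Inventory(plots, species_pool, origin_year)
    return inventory, normals


@dataclass(frozen=True)
class MagnitudeDistribution:
    """Mixture model for the proportion of basal area killed by an event.

    An atom at 0 (events that kill nothing), an atom at 1 (stand-replacing
    events), and a Beta(a, b) distribution for the partial kills between.
    """

    zero_prob: float = 0.0
    one_prob: float = 0.0
    beta_a: float = 1.5
    beta_b: float = 1.5

    def __post_init__(self) -> None:
        if self.zero_prob + self.one_prob > 1:
            raise ValueError("atom probabilities exceed 1")

    def sample(self, rng: np.random.Generator) -> float:
        u = rng.random()
        if u < self.zero_prob:
            return 0.0
        if u < self.zero_prob + self.one_prob:
            return 1.0
        return float(rng.beta(self.beta_a, self.beta_b))


#: Default per-class magnitude models: harvests always remove trees (no
#: atom at 0, occasional complete removal); fire often spares the stand;
#: stress events kill nothing 40% of the time and are never stand-replacing.
DEFAULT_MAGNITUDES: dict[str, MagnitudeDistribution] = {
    "harvest": MagnitudeDistribution(zero_prob=0.0, one_prob=0.02, beta_a=2.0, beta_b=1.2),
    "fire": MagnitudeDistribution(zero_prob=0.30, one_prob=0.05, beta_a=1.2, beta_b=1.5),
    "stress": MagnitudeDistribution(zero_prob=0.40, one_prob=0.0, beta_a=1.1, beta_b=2.5),
}


def make_remeasurement_data(
    true_probs: dict[str, float],
    magnitude_distributions: dict[str, MagnitudeDistribution] | None,
    n_plots: int,
    seed: int,
    reserved_fraction: float = 0.0,
):
    """Simulate a repeat-measurement table with known ground truth.

    Each plot is independently disturbed by each class with its true
    10-year probability; disturbed plots get one magnitude draw per class
    from that class's distribution.  Plots with no event get a single
    ``none`` record.  Classes are independent, matching per-class
    proportion estimation.
    """
    from .io_formats import RemeasurementTable  # local import to avoid a cycle

    magnitude_distributions = magnitude_distributions or DEFAULT_MAGNITUDES
    for cls, p in true_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"true probability for {cls} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    classes = list(true_probs)
    for i in range(n_plots):
        pid = f"R{i + 1:05d}"
        reserved = bool(rng.random() < reserved_fraction)
        hit_any = False
        for cls in classes:
            if rng.random() < true_probs[cls]:
                hit_any = True
                mag = magnitude_distributions[cls].sample(rng)
                rows.append((pid, cls, mag, reserved))
        if not hit_any:
            rows.append((pid, "none", 0.0, reserved))
    import pandas as pd

    df = pd.DataFrame(
        rows, columns=["plot_id", "disturbance_class", "prop_ba_killed", "reserved"]
    )
    return RemeasurementTable(df)


def make_climate_scenario(
    normals: dict[str, np.ndarray],
    delta_by_horizon: dict[str, float] | None = None,
    shape: str = "linear",
    seed: int = 0,
    *,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    origin_year: int = 2016,
    horizon_years: int = 100,
    cycle_years: int = 10,
) -> ClimateTrajectory:
    """Build per-plot climate trajectories at cycle resolution.

    ``shape``:

    - ``"constant"`` — the no-change scenario: every year equals the
      plot's normals (deltas are ignored).
    - ``"linear"`` — each metric moves linearly from its normal to
      normal + delta at the horizon.
    - ``"logistic"`` — an S-shaped approach to the same endpoint
      (normalized logistic, midpoint at half horizon), monotone for each
      metric.

    Deltas default to the RCP6.0-consistent warming
    (:data:`DEFAULT_WARMING_DELTA`).  The trajectory is deterministic;
    ``seed`` is accepted for interface uniformity.
    """
    if shape not in ("constant", "linear", "logistic"):
        raise ValueError(f"unknown scenario shape {shape!r}")
    delta = dict(DEFAULT_WARMING_DELTA if delta_by_horizon is None else delta_by_horizon)
    years = np.arange(origin_year, origin_year + horizon_years + 1, cycle_years)
    t = (years - origin_year) / horizon_years  # 0..1
    if shape == "constant":
        ramp = np.zeros_like(t, dtype=float)
    elif shape == "linear":
        ramp = t.astype(float)
    else:  # logistic, normalized so ramp(0)=0 and ramp(1)=1
        k = 8.0
        raw = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
        raw0 = 1.0 / (1.0 + math.exp(k * 0.5))
        raw1 = 1.0 / (1.0 + math.exp(-k * 0.5))
        ramp = (raw - raw0) / (raw1 - raw0)
    values: dict[str, np.ndarray] = {}
    norm_arrays: dict[str, np.ndarray] = {}
    delta_vec = np.array([delta.get(m, 0.0) for m in metrics])
    for pid, base in normals.items():
        base = np.asarray(base, dtype=float)
        values[pid] = base[None, :] + ramp[:, None] * delta_vec[None, :]
        norm_arrays[pid] = base
    return ClimateTrajectory(
        metrics=list(metrics), years=years, values=values, normals=norm_arrays
    )
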