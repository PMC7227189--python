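"""CSV schemas, run configuration, and result tables.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimals (the FIA Datamart convention).  Schemas:

- ``plots.csv``: plot_id, elevation_m, reserved, expansion_factor_ha
- ``trees.csv``: plot_id, species, dbh_cm, height_m, tph
- ``species.csv``: code, max_dbh_cm, max_increment_cm_yr, height_k,
  height_cap_m, wood_density_kg_m3, crown_factor, base_max_sdi,
  form_factor, plus ``opt_<metric>`` / ``breadth_<metric>`` niche columns
- ``remeasure.csv``: plot_id, disturbance_class, prop_ba_killed, reserved
- ``climate.csv``: plot_id, year (calendar year, or ``normal`` for the
  1960-1990 normals row), one column per metric
- ``results.csv``: scenario, dclim_level, disturbance_level, replicate,
  year, variable, species, value (long format; carbon rows carry species
  ``ALL``)

Validation errors always name the offending column or row; the only
silent coercion is case-folding of disturbance class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ClimateTrajectory, Inventory, Plot, SpeciesParams, TreeCohort
from .disturbance import DISTURBANCE_CLASSES

__all__ = [
    "SchemaError",
    "ValidationError",
    "RemeasurementTable",
    "RunConfig",
    "read_inventory",
    "write_inventory",
    "read_remeasurements",
    "write_remeasurements",
    "read_climate",
    "write_climate",
    "read_config",
    "write_config",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = [
    "scenario",
    "dclim_level",
    "disturbance_level",
    "replicate",
    "year",
    "variable",
    "species",
    "value",
]


class SchemaError(ValueError):
    """A required column is missing or a file is malformed."""


class ValidationError(ValueError):
    """Row-level contents violate an invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


_VALID_CLASSES = set(DISTURBANCE_CLASSES) | {"none"}


@dataclass
class RemeasurementTable:
    """Validated repeat-measurement records.

    One or more records per plot: each disturbance class observed on the
    plot yields a record; a plot with no disturbance yields a single
    ``none`` record with proportion 0.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        required = ["plot_id", "disturbance_class", "prop_ba_killed"]
        _require_columns(df, required, "remeasurement table")
        if "reserved" not in df.columns:
            df["reserved"] = False
        df["disturbance_class"] = df["disturbance_class"].astype(str).str.lower()
        bad_cls = df[~df["disturbance_class"].isin(_VALID_CLASSES)]
        if len(bad_cls):
            labels = sorted(bad_cls["disturbance_class"].unique())
            raise ValidationError(
                f"unknown disturbance class label(s) {labels} "
                f"(rows {bad_cls.index.tolist()[:10]})"
            )
        props = pd.to_numeric(df["prop_ba_killed"], errors="coerce")
        bad = df[(props < 0) | (props > 1) | props.isna()]
        if len(bad):
            raise ValidationError(
                f"prop_ba_killed outside [0, 1] in rows {bad.index.tolist()[:10]}"
            )
        df["prop_ba_killed"] = props
        none_nonzero = df[
            (df["disturbance_class"] == "none") & (df["prop_ba_killed"] != 0)
        ]
        if len(none_nonzero):
            raise ValidationError(
                "class 'none' implies prop_ba_killed = 0; violated in rows "
                f"{none_nonzero.index.tolist()[:10]}"
            )
        df["reserved"] = df["reserved"].astype(bool)
        self.records = df

    @property
    def n_plots(self) -> int:
        return int(self.records["plot_id"].nunique())

    def of_class(self, disturbance_class: str) -> pd.DataFrame:
        return self.records[self.records["disturbance_class"] == disturbance_class]


def read_remeasurements(path) -> RemeasurementTable:
    """Read and validate a remeasurement CSV.

    Proportions outside [0, 1] and unknown class labels are errors, not
    clipped; class labels are case-folded (``Fire`` -> ``fire``).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["plot_id", "disturbance_class", "prop_ba_killed"], path)
    return RemeasurementTable(df)


def write_remeasurements(table: RemeasurementTable, path) -> None:
    table.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inventory I/O


def _species_to_row(sp: SpeciesParams) -> dict:
    row = {
        "code": sp.code,
        "max_dbh_cm": sp.max_dbh,
        "max_increment_cm_yr": sp.max_increment,
        "height_k": sp.height_k,
        "height_cap_m": sp.height_cap,
        "wood_density_kg_m3": sp.wood_density,
        "crown_factor": sp.crown_factor,
        "base_max_sdi": sp.base_max_sdi,
        "form_factor": sp.form_factor,
    }
    for m, v in sp.optimum.items():
        row[f"opt_{m}"] = v
    for m, v in sp.breadth.items():
        row[f"breadth_{m}"] = v
    return row


def _species_from_row(row: pd.Series) -> SpeciesParams:
    optimum = {}
    breadth = {}
    for col in row.index:
        if col.startswith("opt_"):
            optimum[col[4:]] = float(row[col])
        elif col.startswith("breadth_"):
            breadth[col[8:]] = float(row[col])
    return SpeciesParams(
        code=str(row["code"]),
        optimum=optimum,
        breadth=breadth,
        max_dbh=float(row["max_dbh_cm"]),
        max_increment=float(row["max_increment_cm_yr"]),
        height_k=float(row["height_k"]),
        height_cap=float(row["height_cap_m"]),
        wood_density=float(row["wood_density_kg_m3"]),
        crown_factor=float(row["crown_factor"]),
        base_max_sdi=float(row["base_max_sdi"]),
        form_factor=float(row["form_factor"]),
    )


_SPECIES_REQUIRED = [
    "code",
    "max_dbh_cm",
    "max_increment_cm_yr",
    "height_k",
    "height_cap_m",
    "wood_density_kg_m3",
    "crown_factor",
    "base_max_sdi",
    "form_factor",
]


def read_inventory(plot_path, tree_path, species_path, origin_year: int = 2016) -> Inventory:
    """Read plots, trees and species CSVs into a validated Inventory.

    Each tree row becomes one cohort on its plot.  A tree row referencing
    an absent plot id, or an unknown species code, is a validation error.
    """
    plots_df = pd.read_csv(plot_path)
    _require_columns(
        plots_df, ["plot_id", "elevation_m", "reserved", "expansion_factor_ha"], plot_path
    )
    trees_df = pd.read_csv(tree_path)
    _require_columns(trees_df, ["plot_id", "species", "dbh_cm", "height_m", "tph"], tree_path)
    species_df = pd.read_csv(species_path)
    _require_columns(species_df, _SPECIES_REQUIRED, species_path)

    species_pool = {}
    for _, row in species_df.iterrows():
        sp = _species_from_row(row)
        species_pool[sp.code] = sp

    unknown_species = sorted(set(trees_df["species"].astype(str)) - set(species_pool))
    if unknown_species:
        raise ValidationError(f"{tree_path}: unknown species code(s) {unknown_species}")

    plot_ids = set(plots_df["plot_id"].astype(str))
    orphan = sorted(set(trees_df["plot_id"].astype(str)) - plot_ids)
    if orphan:
        raise ValidationError(f"{tree_path}: tree rows reference absent plot id(s) {orphan}")

    bad_exp = plots_df[plots_df["expansion_factor_ha"] <= 0]
    if len(bad_exp):
        raise ValidationError(
            f"{plot_path}: expansion_factor_ha must be > 0 "
            f"(rows {bad_exp.index.tolist()[:10]})"
        )

    cohorts_by_plot: dict[str, list[TreeCohort]] = {pid: [] for pid in plot_ids}
    for _, row in trees_df.iterrows():
        cohorts_by_plot[str(row["plot_id"])].append(
            TreeCohort(
                species=str(row["species"]),
                density=float(row["tph"]),
                dbh=float(row["dbh_cm"]),
                height=float(row["height_m"]),
                establishment_year=origin_year,
                establishment_climate=None,
            )
        )
    plots = [
        Plot(
            id=str(row["plot_id"]),
            elevation=float(row["elevation_m"]),
            reserved=bool(row["reserved"]),
            expansion_factor=float(row["expansion_factor_ha"]),
            cohorts=cohorts_by_plot[str(row["plot_id"])],
        )
        for _, row in plots_df.iterrows()
    ]
    return Inventory(plots, species_pool, origin_year)


def write_inventory(inventory: Inventory, plot_path, tree_path, species_path) -> None:
    pd.DataFrame(
        [
            {
                "plot_id": p.id,
                "elevation_m": p.elevation,
                "reserved": p.reserved,
                "expansion_factor_ha": p.expansion_factor,
            }
            for p in inventory.plots
        ]
    ).to_csv(plot_path, index=False)
    pd.DataFrame(
        [
            {
                "plot_id": p.id,
                "species": c.species,
                "dbh_cm": c.dbh,
                "height_m": c.height,
                "tph": c.density,
            }
            for p in inventory.plots
            for c in p.cohorts
        ],
        columns=["plot_id", "species", "dbh_cm", "height_m", "tph"],
    ).to_csv(tree_path, index=False)
    pd.DataFrame(
        [_species_to_row(sp) for sp in inventory.species_pool.values()]
    ).to_csv(species_path, index=False)


# ---------------------------------------------------------------------------
# Climate I/O


def write_climate(trajectory: ClimateTrajectory, path) -> None:
    rows = []
    for pid in trajectory.values:
        rows.append(
            {"plot_id": pid, "year": "normal"}
            | dict(zip(trajectory.metrics, np.asarray(trajectory.normals[pid]).tolist()))
        )
        for i, year in enumerate(trajectory.years):
            rows.append(
                {"plot_id": pid, "year": str(int(year))}
                | dict(zip(trajectory.metrics, trajectory.values[pid][i].tolist()))
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_climate(path) -> ClimateTrajectory:
    df = pd.read_csv(path, dtype={"plot_id": str, "year": str})
    _require_columns(df, ["plot_id", "year"], path)
    metrics = [c for c in df.columns if c not in ("plot_id", "year")]
    if not metrics:
        raise SchemaError(f"{path}: no climate metric columns found")
    normals_df = df[df["year"] == "normal"]
    series_df = df[df["year"] != "normal"].copy()
    if normals_df.empty:
        raise ValidationError(f"{path}: no 'normal' rows found")
    series_df["year"] = series_df["year"].astype(int)
    years = np.sort(series_df["year"].unique())
    values = {}
    normals = {}
    for pid, grp in series_df.groupby("plot_id", sort=True):
        grp = grp.sort_values("year")
        if not np.array_equal(grp["year"].to_numpy(), years):
            raise ValidationError(f"{path}: plot {pid} does not cover all years")
        values[pid] = grp[metrics].to_numpy(dtype=float)
    for _, row in normals_df.iterrows():
        normals[str(row["plot_id"])] = row[metrics].to_numpy(dtype=float)
    missing = sorted(set(values) - set(normals))
    if missing:
        raise ValidationError(f"{path}: plots missing normals rows: {missing[:10]}")
    return ClimateTrajectory(metrics=metrics, years=years, values=values, normals=normals)


# ---------------------------------------------------------------------------
# Run configuration


def _parse_dclim_level(level) -> float | None:
    # YAML 1.1 reads a bare Off as boolean False; accept it as "rule off"
    if level is None or level is False or (
        isinstance(level, str) and level.lower() == "off"
    ):
        return None
    return float(level)


def dclim_label(multiplier: float | None) -> str:
    """Canonical string label for a dClim level (``off``, ``2.0``, ``1.0``,
    ``0.5``)."""
    return "off" if multiplier is None else f"{multiplier:.1f}"


def disturbance_label(multiplier: float) -> str:
    return f"{multiplier:g}"


@dataclass(frozen=True)
class RunConfig:
    """Settings of a projection experiment.

    The factorial design is the cross of ``climate_scenarios``,
    ``dclim_levels`` (``None`` = rule off), ``disturbance_levels`` and
    ``n_replicates`` replicate disturbance streams.  The horizon must be
    divisible by the cycle length.  ``common_random_numbers`` reuses the
    same disturbance draw stream across cells sharing a replicate index,
    enabling paired comparisons; set it False for fully independent runs.
    """

    climate_scenarios: tuple[str, ...] = ("none", "warming")
    dclim_levels: tuple[float | None, ...] = (None, 2.0, 1.0, 0.5)
    disturbance_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    n_replicates: int = 10
    cycle_years: int = 10
    horizon_years: int = 100
    master_seed: int = 0
    snag_retention: float = 0.7
    stocking_threshold: float = 40.0
    planting_density: float = 1235.0
    max_regen_species: int = 4
    sdi_floor: float = 0.2
    warming_delta: dict = field(default_factory=lambda: {"mat": 2.2, "map": 50.0})
    warming_shape: str = "linear"
    common_random_numbers: bool = True
    dclim_require_all: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years % self.cycle_years != 0:
            raise ValueError("horizon must be divisible by the cycle length")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.snag_retention <= 1.0:
            raise ValueError("snag retention must be in [0, 1]")
        for s in self.climate_scenarios:
            if s not in ("none", "warming"):
                raise ValueError(f"unknown climate scenario {s!r}")

    @property
    def n_cycles(self) -> int:
        return self.horizon_years // self.cycle_years


def read_config(path) -> RunConfig:
    """Read a YAML run configuration; missing keys take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "climate_scenarios" in raw:
        raw["climate_scenarios"] = tuple(raw["climate_scenarios"])
    if "dclim_levels" in raw:
        raw["dclim_levels"] = tuple(_parse_dclim_level(v) for v in raw["dclim_levels"])
    if "disturbance_levels" in raw:
        raw["disturbance_levels"] = tuple(float(v) for v in raw["disturbance_levels"])
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    payload = {
        "climate_scenarios": list(config.climate_scenarios),
        "dclim_levels": [dclim_label(v) for v in config.dclim_levels],
        "disturbance_levels": list(config.disturbance_levels),
        "n_replicates": config.n_replicates,
        "cycle_years": config.cycle_years,
        "horizon_years": config.horizon_years,
        "master_seed": config.master_seed,
        "snag_retention": config.snag_retention,
        "stocking_threshold": config.stocking_threshold,
        "planting_density": config.planting_density,
        "max_regen_species": config.max_regen_species,
        "sdi_floor": config.sdi_floor,
        "warming_delta": dict(config.warming_delta),
        "warming_shape": config.warming_shape,
        "common_random_numbers": config.common_random_numbers,
        "dclim_require_all": config.dclim_require_all,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Results I/O


def write_results(result_table: pd.DataFrame, path) -> None:
    """Write the long-format results table; an empty table yields a
    header-only file."""
    df = result_table.reindex(columns=RESULT_COLUMNS)
    # shortest round-tripping decimal representation: re-reading the file
    # recovers every float bit-exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "scenario": str,
            "dclim_level": str,
            "disturbance_level": str,
            "species": str,
            "variable": str,
        },
        keep_default_na=False,
        na_values=[],
        float_precision="round_trip",
    )
    if len(df):
        df["replicate"] = df["replicate"].astype(int)
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
    return df
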