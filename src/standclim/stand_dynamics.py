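"""Cohort growth, density-dependent mortality, regeneration and snag aging.

Density is measured in Reineke's stand density index (SDI): the summation
form ``sum(density * (DBH / 25.4) ** 1.605)`` over live cohorts, so a
stand of 500 TPH at the 25.4 cm reference diameter has SDI 500.  The
carrying capacity is the viability-modified maximum SDI; self-thinning
holds stands at or below 85% of it, and stocking percent (SDI relative to
the effective maximum) triggers planting when it falls below 40%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .climate_mortality import ViabilityModel
from .core import (
    BREAST_HEIGHT_M,
    REINEKE_EXPONENT,
    REINEKE_REFERENCE_DBH_CM,
    Plot,
    SnagRecord,
    SpeciesParams,
    TreeCohort,
)

__all__ = [
    "Plot",
    "RegenerationConfig",
    "stand_sdi",
    "grow_cohorts",
    "density_mortality",
    "stocking_percent",
    "regenerate",
    "age_snags",
    "SELF_THINNING_RATIO",
]

#: Fraction of the effective maximum SDI at which self-thinning holds stands.
SELF_THINNING_RATIO = 0.85

#: Competition sensitivity of the diameter increment to the SDI ratio.
_COMPETITION_SLOPE = 0.7


@dataclass(frozen=True)
class RegenerationConfig:
    """Artificial regeneration (planting) settings.

    Planting fires when stocking falls strictly below ``stocking_threshold``
    percent; up to ``max_species`` climatically suited species (viability >=
    ``eligibility_threshold``) are planted at ``planting_density`` TPH
    total, split equally, as seedlings of the given size.  No seed source
    is required: any pool species may establish, which lets species migrate
    into a plot as climate shifts.
    """

    stocking_threshold: float = 40.0  # percent
    planting_density: float = 1235.0  # TPH, total across species
    max_species: int = 4
    eligibility_threshold: float = 0.5
    seedling_dbh: float = 0.5  # cm
    seedling_height: float = BREAST_HEIGHT_M  # m

    def __post_init__(self) -> None:
        if not 0 < self.stocking_threshold < 100:
            raise ValueError("stocking threshold must be in (0, 100)")
        if self.planting_density <= 0:
            raise ValueError("planting density must be > 0")


def stand_sdi(plot: Plot) -> float:
    """Summation stand density index (TPH at 25.4 cm) of the live cohorts."""
    return sum(
        c.density * (c.dbh / REINEKE_REFERENCE_DBH_CM) ** REINEKE_EXPONENT
        for c in plot.cohorts
        if c.density > 0 and c.dbh > 0
    )


def grow_cohorts(
    plot: Plot,
    species_params: dict[str, SpeciesParams],
    sdi_ratio: float,
    cycle_years: int = 10,
) -> Plot:
    """Grow every cohort for ``cycle_years`` annual steps, in place.

    The annual diameter increment is the open-grown maximum tapered
    linearly to zero at the species' asymptotic DBH and reduced by
    competition::

        dDBH = max_increment * (1 - DBH / max_dbh) * max(0, 1 - 0.7 * sdi_ratio)

    clipped at zero.  Height follows the species' saturating
    height-diameter curve and is hard-capped at the species height cap;
    a tree at the cap stays there regardless of diameter growth.
    ``sdi_ratio`` (stand SDI over effective maximum SDI) is held fixed
    over the cycle.
    """
    if sdi_ratio < 0:
        raise ValueError("sdi_ratio must be >= 0")
    competition = max(0.0, 1.0 - _COMPETITION_SLOPE * sdi_ratio)
    for cohort in plot.cohorts:
        sp = species_params[cohort.species]
        dbh = cohort.dbh
        for _ in range(cycle_years):
            inc = sp.max_increment * (1.0 - dbh / sp.max_dbh) * competition
            dbh += max(0.0, inc)
        cohort.dbh = min(dbh, sp.max_dbh)
        # Height never shrinks and never exceeds the cap.
        cohort.height = min(max(cohort.height, sp.height_at(cohort.dbh)), sp.height_cap)
    return plot


def density_mortality(plot: Plot, effective_max_sdi: float, year: int = 0) -> Plot:
    """Self-thinning against the viability-modified carrying capacity.

    If stand SDI exceeds ``SELF_THINNING_RATIO`` times the effective
    maximum, all cohort densities are scaled by the single factor that
    brings SDI back to exactly that ceiling; the killed density moves to
    the snag pool with dimensions frozen at death.
    """
    if effective_max_sdi <= 0:
        raise ValueError("effective max SDI must be > 0")
    sdi = stand_sdi(plot)
    ceiling = SELF_THINNING_RATIO * effective_max_sdi
    if sdi <= ceiling:
        return plot
    factor = ceiling / sdi
    for cohort in plot.cohorts:
        killed = cohort.density * (1.0 - factor)
        if killed > 0:
            plot.snags.append(
                SnagRecord(cohort.species, killed, cohort.dbh, cohort.height, year)
            )
        cohort.density *= factor
    return plot


def stocking_percent(plot: Plot, effective_max_sdi: float) -> float:
    """Stocking as percent of the effective maximum SDI."""
    if effective_max_sdi <= 0:
        raise ValueError("effective max SDI must be > 0")
    return 100.0 * stand_sdi(plot) / effective_max_sdi


def regenerate(
    plot: Plot,
    climate_now: dict[str, float],
    viability_model: ViabilityModel,
    regen_config: RegenerationConfig,
    year: int,
) -> Plot:
    """Plant climatically suited seedlings on an understocked plot, in place.

    Up to ``max_species`` pool species with viability >= the eligibility
    threshold are selected, highest scores first (ties broken by species
    code); the total planting density is split equally among them.  New
    cohorts carry ``climate_now`` as their establishment climate, so they
    are immune to the dClim rule until climate moves a further window.
    If no species is viable, nothing is planted.
    """
    scored = sorted(
        (
            (-viability_model.score(code, climate_now), code)
            for code in viability_model.species_pool
        ),
    )
    chosen = [
        code
        for neg, code in scored
        if -neg >= regen_config.eligibility_threshold
    ][: regen_config.max_species]
    if not chosen:
        return plot
    per_species = regen_config.planting_density / len(chosen)
    for code in chosen:
        plot.cohorts.append(
            TreeCohort(
                species=code,
                density=per_species,
                dbh=regen_config.seedling_dbh,
                height=regen_config.seedling_height,
                establishment_year=year,
                establishment_climate=dict(climate_now),
            )
        )
    return plot


def age_snags(plot: Plot, retention_per_cycle: float) -> Plot:
    """Decay the snag pool: each record keeps ``retention_per_cycle`` of its
    density; fallen (zero-density) records are dropped."""
    if not 0.0 <= retention_per_cycle <= 1.0:
        raise ValueError("snag retention must be in [0, 1]")
    for snag in plot.snags:
        snag.density *= retention_per_cycle
    plot.snags = [s for s in plot.snags if s.density > 0.0]
    return plot
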