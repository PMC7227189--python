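"""Climate-driven mortality pathways.

Three mechanisms, acting independently:

1. **Envelope mortality** — a species whose viability score at the current
   climate falls below the threshold (0.5) loses density each cycle on a
   linear ramp (``score / threshold``); species rarely occur where their
   viability score is below 0.5, so the ramp represents gradual attrition
   of a maladapted cohort.
2. **Viability-modified carrying capacity** — the plot's maximum stand
   density index is scaled by the basal-area-weighted mean viability of its
   cohorts, so climates favouring low-density species shrink the capacity
   and induce density-dependent mortality downstream.
3. **The dClim elevation-window rule** — a whole cohort dies suddenly when
   the climate change since its establishment exceeds the climate
   difference across a +300 m / -150 m elevation window (roughly one seed
   zone).  The rule is independent of viability: a killed cohort may be
   replaced by a new cohort of the same species, which is then immune
   until the climate moves another window from its *new* baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ClimateGradient, SpeciesParams, TreeCohort

__all__ = [
    "VIABILITY_THRESHOLD",
    "ViabilityModel",
    "DClimConfig",
    "TreeCohort",
    "viability",
    "envelope_survival_multiplier",
    "effective_max_sdi",
    "dclim_triggered",
    "reset_establishment",
]

#: Viability score below which a species is considered outside its envelope.
VIABILITY_THRESHOLD = 0.5


def viability(species: SpeciesParams, climate: dict[str, float]) -> float:
    """Viability score in [0, 1] of ``climate`` for ``species``.

    Separable Gaussian niche: product over metrics of
    ``exp(-0.5 * ((x - optimum) / breadth) ** 2)``.  The score is 1 at the
    niche optimum and symmetric about it in each metric.

    Raises
    ------
    ValueError
        If the climate vector does not cover the species' niche metrics.
    """
    missing = set(species.optimum) - set(climate)
    if missing:
        raise ValueError(
            f"climate vector missing metrics {sorted(missing)} "
            f"required by species {species.code}"
        )
    z2 = 0.0
    for metric, opt in species.optimum.items():
        z = (climate[metric] - opt) / species.breadth[metric]
        z2 += z * z
    return math.exp(-0.5 * z2)


@dataclass(frozen=True)
class ViabilityModel:
    """Maps (species, climate) -> viability score for a species pool."""

    species_pool: dict[str, SpeciesParams]
    threshold: float = VIABILITY_THRESHOLD

    def score(self, species_code: str, climate: dict[str, float]) -> float:
        return viability(self.species_pool[species_code], climate)

    def is_viable(self, species_code: str, climate: dict[str, float]) -> bool:
        return self.score(species_code, climate) >= self.threshold


def envelope_survival_multiplier(score: float, threshold: float = VIABILITY_THRESHOLD) -> float:
    """Per-cycle survival fraction from the viability envelope.

    1 at or above the threshold; a linear ramp ``score / threshold`` below
    it, reaching 0 at score 0 (the cohort dies within the cycle).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"viability score must be in [0, 1], got {score}")
    if score >= threshold:
        return 1.0
    return score / threshold


@dataclass(frozen=True)
class DClimConfig:
    """Configuration of the dClim elevation-window mortality rule.

    The per-metric trigger threshold is
    ``tau_k = multiplier * |gradient_k| * (rise + drop)``: the climate
    difference across the elevation window, scaled by the sensitivity
    multiplier.  ``multiplier=None`` ("off") disables the rule.  Halving
    the multiplier halves the tolerated change and so *increases*
    climate-related mortality; doubling it decreases mortality.
    """

    gradients: ClimateGradient
    multiplier: float | None = 1.0
    rise: float = 300.0  # m
    drop: float = 150.0  # m

    def __post_init__(self) -> None:
        if self.multiplier is not None and self.multiplier <= 0:
            raise ValueError("dClim multiplier must be > 0 or None (off)")
        if self.rise < 0 or self.drop < 0:
            raise ValueError("elevation window must be nonnegative")

    @property
    def enabled(self) -> bool:
        return self.multiplier is not None

    @property
    def window_span(self) -> float:
        """Total elevation span (m) of the window (rise + drop)."""
        return self.rise + self.drop

    def thresholds(self) -> dict[str, float]:
        """Per-metric climate-change thresholds tau_k (metric units)."""
        if self.multiplier is None:
            raise ValueError("dClim rule is off; thresholds are undefined")
        return {
            m: self.multiplier * abs(r) * self.window_span
            for m, r in self.gradients.rates.items()
        }


def dclim_triggered(
    cohort: TreeCohort,
    climate_now: dict[str, float],
    dclim_config: DClimConfig,
    require_all: bool = False,
) -> bool:
    """Whether the dClim rule kills ``cohort`` under ``climate_now``.

    Triggers when the absolute climate change since establishment exceeds
    the window threshold for ANY metric (default; set ``require_all`` for
    the ALL-metrics variant).  The caller must skip this check entirely
    when the rule is off.
    """
    if cohort.establishment_climate is None:
        raise ValueError("cohort has no establishment climate recorded")
    taus = dclim_config.thresholds()
    missing = set(taus) - set(cohort.establishment_climate)
    if missing:
        raise ValueError(f"establishment climate missing metrics {sorted(missing)}")
    exceeded = (
        abs(climate_now[m] - cohort.establishment_climate[m]) > tau
        for m, tau in taus.items()
    )
    return all(exceeded) if require_all else any(exceeded)


def reset_establishment(
    cohort: TreeCohort, climate_now: dict[str, float], year: int
) -> TreeCohort:
    """Rebase a (newly regenerated) cohort's climate memory to now.

    The returned cohort is immune to the dClim rule until the climate moves
    a further full window from ``climate_now``.
    """
    out = cohort.copy()
    out.establishment_climate = dict(climate_now)
    out.establishment_year = year
    return out


def effective_max_sdi(
    plot,
    climate: dict[str, float],
    viability_model: ViabilityModel,
    floor: float = 0.2,
) -> float:
    """Viability-modified maximum stand density index (TPH) for a plot.

    The base capacity is the basal-area-weighted mean of the species'
    ``base_max_sdi`` (pool mean for an empty plot); it is scaled by the
    basal-area-weighted mean viability, floored at ``floor`` to avoid a
    zero-capacity singularity.  Capacity therefore drops when climate
    favours species that occur at lower stand densities.
    """
    pool = viability_model.species_pool
    weights = [(c, c.basal_area) for c in plot.cohorts]
    total_ba = sum(w for _, w in weights)
    if total_ba > 0:
        base = sum(pool[c.species].base_max_sdi * w for c, w in weights) / total_ba
        mean_viab = sum(
            viability_model.score(c.species, climate) * w for c, w in weights
        ) / total_ba
    else:
        base = sum(sp.base_max_sdi for sp in pool.values()) / len(pool)
        mean_viab = sum(
            viability(sp, climate) for sp in pool.values()
        ) / len(pool)
    return base * max(floor, mean_viab)
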