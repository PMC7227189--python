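"""Empirical disturbance regimes: estimation, scaling, sampling, application.

The regime is estimated from repeat inventory measurements.  For each
disturbance class (harvest, fire, stress) the 10-year probability is the
proportion of remeasured plots that experienced the class, and the
magnitude — the proportion of plot basal area killed — is kept as the
empirical cumulative distribution of the observed proportions.  A class
with no observed events gets probability 0 and a degenerate distribution
at 0 (the all-quiet analogue of a fire-free coastal forest).

During simulation each class is drawn independently per plot per cycle
(Bernoulli at the scaled probability), the magnitude by inverse-transform
sampling from the class ECDF; harvest is never drawn on reserved plots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import Plot, SnagRecord

__all__ = [
    "DISTURBANCE_CLASSES",
    "DisturbanceRegime",
    "DisturbanceEvent",
    "estimate_regime",
    "scale_regime",
    "sample_cycle_events",
    "apply_event",
]

#: Event classes, in the fixed order they are drawn and applied each cycle.
DISTURBANCE_CLASSES = ("harvest", "fire", "stress")


@dataclass(frozen=True)
class DisturbanceEvent:
    """One disturbance hitting one plot in one cycle."""

    disturbance_class: str
    proportion_ba_killed: float
    cycle_year: int

    def __post_init__(self) -> None:
        if self.disturbance_class not in DISTURBANCE_CLASSES:
            raise ValueError(f"unknown disturbance class {self.disturbance_class!r}")
        if not 0.0 <= self.proportion_ba_killed <= 1.0:
            raise ValueError("proportion of basal area killed must be in [0, 1]")


@dataclass(frozen=True)
class DisturbanceRegime:
    """Per-class 10-year disturbance probability and magnitude ECDF.

    ``probabilities[cls]`` is exactly ``n_disturbed[cls] / n_remeasured``
    for an estimated regime (a scaled regime keeps the counts of its
    parent).  ``magnitudes[cls]`` is the sorted vector of observed
    proportions of basal area killed; the ECDF is the standard
    right-continuous step function through it, and a class with zero
    events has the degenerate vector ``[0.0]``.
    """

    probabilities: dict[str, float]
    magnitudes: dict[str, np.ndarray]
    n_remeasured: int
    n_disturbed: dict[str, int]
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        for cls in DISTURBANCE_CLASSES:
            if cls not in self.probabilities:
                raise ValueError(f"regime missing class {cls!r}")
            p = self.probabilities[cls]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{cls} probability {p} outside [0, 1]")
            mags = np.asarray(self.magnitudes[cls], dtype=float)
            if mags.size == 0:
                raise ValueError(f"{cls} magnitude vector may not be empty")
            if (mags < 0).any() or (mags > 1).any():
                raise ValueError(f"{cls} magnitudes outside [0, 1]")
            self.magnitudes[cls] = np.sort(mags)

    def ecdf(self, disturbance_class: str, x: float | np.ndarray) -> np.ndarray:
        """Right-continuous ECDF of the class magnitude, evaluated at x."""
        mags = self.magnitudes[disturbance_class]
        return np.searchsorted(mags, x, side="right") / mags.size

    def sample_magnitude(self, disturbance_class: str, u: float) -> float:
        """Inverse-transform sample: the generalized inverse ECDF at u."""
        mags = self.magnitudes[disturbance_class]
        idx = min(int(math.floor(u * mags.size)), mags.size - 1)
        return float(mags[idx])

    def to_json(self, path) -> None:
        payload = {
            "n_remeasured": self.n_remeasured,
            "multiplier": self.multiplier,
            "classes": {
                cls: {
                    "probability": self.probabilities[cls],
                    "n_disturbed": self.n_disturbed[cls],
                    "magnitudes": self.magnitudes[cls].tolist(),
                }
                for cls in DISTURBANCE_CLASSES
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DisturbanceRegime":
        with open(path) as fh:
            payload = json.load(fh)
        classes = payload["classes"]
        return cls(
            probabilities={c: classes[c]["probability"] for c in DISTURBANCE_CLASSES},
            magnitudes={
                c: np.asarray(classes[c]["magnitudes"], dtype=float)
                for c in DISTURBANCE_CLASSES
            },
            n_remeasured=payload["n_remeasured"],
            n_disturbed={c: classes[c]["n_disturbed"] for c in DISTURBANCE_CLASSES},
            multiplier=payload.get("multiplier", 1.0),
        )


def estimate_regime(remeasurements) -> DisturbanceRegime:
    """Estimate the disturbance regime from a remeasurement table.

    Parameters
    ----------
    remeasurements : RemeasurementTable
        Repeat-measurement records (one or more per plot; ``none`` records
        carry no event).

    Returns
    -------
    DisturbanceRegime
        Per-class probability = plots disturbed / plots remeasured, and
        pooled magnitude ECDF over disturbed records only.  Record order
        does not matter.
    """
    df = remeasurements.records
    if df.empty:
        raise ValueError("remeasurement table is empty")
    n_remeasured = df["plot_id"].nunique()
    probabilities: dict[str, float] = {}
    magnitudes: dict[str, np.ndarray] = {}
    n_disturbed: dict[str, int] = {}
    for cls in DISTURBANCE_CLASSES:
        hit = df[df["disturbance_class"] == cls]
        n_dist = hit["plot_id"].nunique()
        n_disturbed[cls] = int(n_dist)
        probabilities[cls] = n_dist / n_remeasured
        if len(hit):
            magnitudes[cls] = np.sort(hit["prop_ba_killed"].to_numpy(dtype=float))
        else:
            magnitudes[cls] = np.array([0.0])  # degenerate ECDF: vertical line at 0
    return DisturbanceRegime(probabilities, magnitudes, int(n_remeasured), n_disturbed)


def scale_regime(regime: DisturbanceRegime, multiplier: float) -> DisturbanceRegime:
    """Scale all class probabilities by ``multiplier`` (capped at 1).

    Magnitude distributions are untouched; only how often events occur
    changes.  Multiplier 1 is the identity, 0 removes all disturbance.
    """
    if multiplier < 0:
        raise ValueError("disturbance multiplier must be >= 0")
    return DisturbanceRegime(
        probabilities={
            cls: min(1.0, multiplier * p) for cls, p in regime.probabilities.items()
        },
        magnitudes={cls: m.copy() for cls, m in regime.magnitudes.items()},
        n_remeasured=regime.n_remeasured,
        n_disturbed=dict(regime.n_disturbed),
        multiplier=multiplier,
    )


def sample_cycle_events(
    regime: DisturbanceRegime,
    plot: Plot,
    rng: np.random.Generator,
    cycle_year: int = 0,
) -> list[DisturbanceEvent]:
    """Draw this cycle's disturbance events for one plot.

    Classes are independent Bernoulli draws at the (scaled) class
    probability; harvest is never drawn on a reserved plot.  Six uniforms
    are always consumed (an occurrence and a magnitude uniform per class,
    in the fixed class order) so that draws stay aligned across scenario
    cells under common random numbers.
    """
    u = rng.random(2 * len(DISTURBANCE_CLASSES))
    events: list[DisturbanceEvent] = []
    for i, cls in enumerate(DISTURBANCE_CLASSES):
        p = regime.probabilities[cls]
        if cls == "harvest" and plot.reserved:
            p = 0.0
        if u[2 * i] < p:
            magnitude = regime.sample_magnitude(cls, u[2 * i + 1])
            events.append(DisturbanceEvent(cls, magnitude, cycle_year))
    return events


def apply_event(plot: Plot, event: DisturbanceEvent) -> Plot:
    """Apply a disturbance to a plot, in place.

    Every cohort's density is multiplied by ``1 - m`` (uniform thinning),
    so live basal area drops by exactly the event's proportion.  For fire
    and stress the killed density becomes snags; harvested trees leave the
    plot entirely.  ``m = 1`` empties the live tree list.
    """
    m = event.proportion_ba_killed
    if m <= 0.0:
        return plot
    to_snags = event.disturbance_class in ("fire", "stress")
    for cohort in plot.cohorts:
        killed = cohort.density * m
        if to_snags and killed > 0:
            plot.snags.append(
                SnagRecord(
                    cohort.species, killed, cohort.dbh, cohort.height, event.cycle_year
                )
            )
        cohort.density -= killed
    if m >= 1.0:
        plot.cohorts = []
    return plot
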