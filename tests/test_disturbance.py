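"""Disturbance regime estimation, scaling, sampling and application."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from standclim import (
    DisturbanceEvent,
    Plot,
    RemeasurementTable,
    TreeCohort,
    apply_event,
    estimate_regime,
    sample_cycle_events,
    scale_regime,
)


def table_from_rows(rows):
    return RemeasurementTable(
        pd.DataFrame(rows, columns=["plot_id", "disturbance_class", "prop_ba_killed"])
    )


def simple_regime(fire_p=0.25, magnitudes=(0.1, 0.4, 0.8)):
    rows = []
    n = 1000
    n_fire = round(fire_p * n)
    for i in range(n_fire):
        rows.append((f"p{i}", "fire", magnitudes[i % len(magnitudes)]))
    for i in range(n_fire, n):
        rows.append((f"p{i}", "none", 0.0))
    return estimate_regime(table_from_rows(rows))


class TestEstimateRegime:
    def test_probability_is_exact_proportion(self):
        rows = [(f"p{i}", "fire", 0.5) for i in range(144)]
        rows += [(f"p{i}", "none", 0.0) for i in range(144, 1000)]
        regime = estimate_regime(table_from_rows(rows))
        assert regime.probabilities["fire"] == pytest.approx(0.144)
        assert regime.n_remeasured == 1000
        assert regime.n_disturbed["fire"] == 144

    def test_no_events_gives_degenerate_ecdf_at_zero(self):
        # a fire-free forest: p = 0 and the magnitude CDF is a vertical
        # line at 0
        rows = [(f"p{i}", "none", 0.0) for i in range(50)]
        regime = estimate_regime(table_from_rows(rows))
        assert regime.probabilities["fire"] == 0.0
        assert np.array_equal(regime.magnitudes["fire"], [0.0])
        assert regime.ecdf("fire", 0.0) == 1.0

    def test_ecdf_matches_sort_and_count_oracle(self, rng):
        mags = rng.uniform(0, 1, 37)
        rows = [(f"p{i}", "stress", m) for i, m in enumerate(mags)]
        rows += [(f"q{i}", "none", 0.0) for i in range(13)]
        regime = estimate_regime(table_from_rows(rows))
        for x in np.concatenate([mags, [0.0, 0.5, 1.0]]):
            expected = np.mean(mags <= x)  # independent count oracle
            assert regime.ecdf("stress", x) == pytest.approx(expected)

    def test_invariant_to_record_order(self, rng):
        rows = [(f"p{i}", "fire", float(rng.uniform())) for i in range(30)]
        rows += [(f"q{i}", "harvest", float(rng.uniform())) for i in range(20)]
        rows += [(f"r{i}", "none", 0.0) for i in range(50)]
        fwd = estimate_regime(table_from_rows(rows))
        rev = estimate_regime(table_from_rows(rows[::-1]))
        assert fwd.probabilities == rev.probabilities
        for cls in ("harvest", "fire", "stress"):
            assert np.array_equal(fwd.magnitudes[cls], rev.magnitudes[cls])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_regime(table_from_rows([]))


class TestScaleRegime:
    def test_zero_multiplier_removes_all_disturbance(self):
        scaled = scale_regime(simple_regime(), 0.0)
        assert all(p == 0.0 for p in scaled.probabilities.values())

    def test_probability_caps_at_one(self):
        regime = simple_regime(fire_p=0.6)
        scaled = scale_regime(regime, 2.0)
        assert scaled.probabilities["fire"] == 1.0

    def test_halving(self):
        regime = simple_regime(fire_p=0.132)
        assert scale_regime(regime, 0.5).probabilities["fire"] == pytest.approx(0.066)

    def test_multiplier_one_is_identity(self):
        regime = simple_regime()
        scaled = scale_regime(regime, 1.0)
        assert scaled.probabilities == regime.probabilities
        for cls in scaled.magnitudes:
            assert np.array_equal(scaled.magnitudes[cls], regime.magnitudes[cls])

    def test_magnitudes_unchanged_by_scaling(self):
        regime = simple_regime()
        scaled = scale_regime(regime, 2.0)
        assert np.array_equal(scaled.magnitudes["fire"], regime.magnitudes["fire"])

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            scale_regime(simple_regime(), -1.0)


class TestSampleCycleEvents:
    def _plot(self, reserved=False):
        return Plot("P", 1000.0, reserved, 2400.0)

    def test_reserved_plot_never_harvested(self, rng):
        rows = [(f"p{i}", "harvest", 0.5) for i in range(90)]
        rows += [(f"p{i}", "none", 0.0) for i in range(90, 100)]
        regime = estimate_regime(table_from_rows(rows))
        plot = self._plot(reserved=True)
        events = [
            e
            for _ in range(10_000)
            for e in sample_cycle_events(regime, plot, rng)
        ]
        assert all(e.disturbance_class != "harvest" for e in events)

    def test_zero_probability_gives_no_events(self, rng):
        regime = scale_regime(simple_regime(), 0.0)
        for _ in range(100):
            assert sample_cycle_events(regime, self._plot(), rng) == []

    def test_event_frequency_matches_binomial(self, rng):
        regime = simple_regime(fire_p=0.25)
        n = 10_000
        hits = sum(
            any(e.disturbance_class == "fire" for e in sample_cycle_events(regime, self._plot(), rng))
            for _ in range(n)
        )
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 3 * se

    def test_inverse_transform_ks_distance(self, rng):
        regime = simple_regime(fire_p=1.0, magnitudes=tuple(np.linspace(0.05, 0.95, 19)))
        draws = np.array(
            [regime.sample_magnitude("fire", u) for u in rng.random(10_000)]
        )
        grid = np.linspace(0, 1, 201)
        sample_cdf = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
        ks = np.max(np.abs(sample_cdf - regime.ecdf("fire", grid)))
        assert ks < 0.05


class TestApplyEvent:
    def _plot(self):
        return Plot(
            "P",
            1000.0,
            False,
            2400.0,
            cohorts=[
                TreeCohort("A", 300.0, 30.0, 25.0, 2016),
                TreeCohort("A", 200.0, 20.0, 18.0, 2016),
            ],
        )

    def test_zero_magnitude_changes_nothing(self):
        plot = self._plot()
        before = plot.live_basal_area
        apply_event(plot, DisturbanceEvent("fire", 0.0, 2026))
        assert plot.live_basal_area == before
        assert plot.snags == []

    def test_total_fire_moves_all_ba_to_snags(self):
        plot = self._plot()
        before = plot.live_basal_area
        apply_event(plot, DisturbanceEvent("fire", 1.0, 2026))
        assert plot.live_basal_area == 0.0
        assert plot.cohorts == []
        assert plot.snag_basal_area == pytest.approx(before, rel=1e-9)

    def test_partial_stress_conserves_basal_area(self):
        # m = 0.4: live BA drops by exactly 40%, snags gain exactly that
        plot = self._plot()
        before = plot.live_basal_area
        apply_event(plot, DisturbanceEvent("stress", 0.4, 2026))
        assert plot.live_basal_area == pytest.approx(0.6 * before, rel=1e-9)
        assert plot.snag_basal_area == pytest.approx(0.4 * before, rel=1e-9)

    def test_harvest_removes_without_snags(self):
        plot = self._plot()
        before = plot.live_basal_area
        apply_event(plot, DisturbanceEvent("harvest", 0.3, 2026))
        assert plot.live_basal_area == pytest.approx(0.7 * before, rel=1e-9)
        assert plot.snags == []

    def test_conservation_over_random_events(self, rng):
        # live-BA loss equals snag-BA gain (fire/stress) or removal (harvest)
        for _ in range(200):
            plot = self._plot()
            cls = ("harvest", "fire", "stress")[rng.integers(3)]
            m = float(rng.random())
            live0, snag0 = plot.live_basal_area, plot.snag_basal_area
            apply_event(plot, DisturbanceEvent(cls, m, 2026))
            loss = live0 - plot.live_basal_area
            gain = plot.snag_basal_area - snag0
            if cls == "harvest":
                assert gain == 0.0
                assert loss == pytest.approx(m * live0, rel=1e-9)
            else:
                assert gain == pytest.approx(loss, rel=1e-9)
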