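"""SDI, growth, self-thinning, stocking, regeneration, snag aging."""

import math

import numpy as np
import pytest

from standclim import (
    Plot,
    RegenerationConfig,
    TreeCohort,
    ViabilityModel,
    age_snags,
    density_mortality,
    grow_cohorts,
    regenerate,
    stand_sdi,
    stocking_percent,
)

from conftest import make_test_species


def plot_with(cohorts):
    return Plot("P", 1000.0, False, 2400.0, cohorts=cohorts)


class TestStandSdi:
    def test_empty_plot_is_zero(self):
        assert stand_sdi(plot_with([])) == 0.0

    def test_reference_diameter(self):
        # 500 TPH at the 25.4 cm reference diameter: SDI = 500
        plot = plot_with([TreeCohort("A", 500.0, 25.4, 20.0, 2016)])
        assert stand_sdi(plot) == pytest.approx(500.0)

    def test_additive_over_cohorts(self, rng):
        cohorts = [
            TreeCohort("A", float(rng.uniform(50, 500)), float(rng.uniform(5, 60)), 20.0, 2016)
            for _ in range(5)
        ]
        total = stand_sdi(plot_with(cohorts))
        singles = sum(stand_sdi(plot_with([c])) for c in cohorts)
        assert total == pytest.approx(singles, rel=1e-12)


class TestGrowth:
    def test_zero_increment_at_max_dbh(self, species, species_pool):
        plot = plot_with([TreeCohort("PINE", 100.0, species.max_dbh, 40.0, 2016)])
        grow_cohorts(plot, species_pool, sdi_ratio=0.0)
        assert plot.cohorts[0].dbh == pytest.approx(species.max_dbh)

    def test_open_grown_seedling_grows_at_max_rate_initially(self, species, species_pool):
        plot = plot_with([TreeCohort("PINE", 100.0, 0.0, 1.37, 2016)])
        grow_cohorts(plot, species_pool, sdi_ratio=0.0, cycle_years=1)
        # one open-grown year from DBH 0: the full maximum increment
        assert plot.cohorts[0].dbh == pytest.approx(species.max_increment)

    def test_height_capped(self, species, species_pool):
        plot = plot_with([TreeCohort("PINE", 100.0, 80.0, species.height_cap, 2016)])
        for _ in range(5):
            grow_cohorts(plot, species_pool, sdi_ratio=0.0)
        assert plot.cohorts[0].height == species.height_cap

    def test_height_never_exceeds_cap_over_long_run(self, species_pool, rng):
        plot = plot_with(
            [
                TreeCohort(code, float(rng.uniform(50, 300)), float(rng.uniform(1, 50)), 2.0, 2016)
                for code in species_pool
            ]
        )
        for _ in range(30):
            grow_cohorts(plot, species_pool, sdi_ratio=float(rng.uniform(0, 2)))
            for c in plot.cohorts:
                assert c.height <= species_pool[c.species].height_cap + 1e-12

    def test_competition_slows_growth(self, species_pool):
        open_plot = plot_with([TreeCohort("PINE", 100.0, 20.0, 15.0, 2016)])
        crowded = plot_with([TreeCohort("PINE", 100.0, 20.0, 15.0, 2016)])
        grow_cohorts(open_plot, species_pool, sdi_ratio=0.0)
        grow_cohorts(crowded, species_pool, sdi_ratio=1.0)
        assert crowded.cohorts[0].dbh < open_plot.cohorts[0].dbh


class TestDensityMortality:
    def test_below_ceiling_is_noop(self):
        plot = plot_with([TreeCohort("A", 100.0, 25.4, 20.0, 2016)])
        density_mortality(plot, effective_max_sdi=1000.0)
        assert plot.cohorts[0].density == 100.0
        assert plot.snags == []

    def test_overshoot_scaled_back_to_ceiling_exactly(self):
        # SDI = 2 x ceiling: densities halve, snags gain the difference
        plot = plot_with(
            [
                TreeCohort("A", 600.0, 25.4, 20.0, 2016),
                TreeCohort("B", 400.0, 25.4, 18.0, 2016),
            ]
        )
        ba_before = plot.live_basal_area
        max_sdi = 1000.0 / 0.85 / 2.0  # ceiling = SDI / 2
        density_mortality(plot, max_sdi)
        assert plot.cohorts[0].density == pytest.approx(300.0, rel=1e-9)
        assert plot.cohorts[1].density == pytest.approx(200.0, rel=1e-9)
        assert stand_sdi(plot) == pytest.approx(0.85 * max_sdi, rel=1e-9)
        assert plot.snag_basal_area == pytest.approx(ba_before / 2, rel=1e-9)

    def test_conservation_random_calls(self, rng):
        for _ in range(200):
            plot = plot_with(
                [
                    TreeCohort("A", float(rng.uniform(10, 800)), float(rng.uniform(5, 60)), 20.0, 2016)
                    for _ in range(int(rng.integers(1, 5)))
                ]
            )
            live0 = plot.live_basal_area
            density_mortality(plot, float(rng.uniform(50, 2000)))
            total = plot.live_basal_area + plot.snag_basal_area
            assert total == pytest.approx(live0, rel=1e-9)


class TestStocking:
    def test_empty_plot_zero_percent(self):
        assert stocking_percent(plot_with([]), 800.0) == 0.0

    def test_forty_percent_boundary(self):
        plot = plot_with([TreeCohort("A", 320.0, 25.4, 20.0, 2016)])
        assert stocking_percent(plot, 800.0) == pytest.approx(40.0)

    def test_linear_in_density(self):
        plot1 = plot_with([TreeCohort("A", 100.0, 30.0, 20.0, 2016)])
        plot2 = plot_with([TreeCohort("A", 200.0, 30.0, 20.0, 2016)])
        assert stocking_percent(plot2, 800.0) == pytest.approx(
            2 * stocking_percent(plot1, 800.0)
        )

    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError):
            stocking_percent(plot_with([]), 0.0)


class TestRegeneration:
    def _pool(self, optima):
        return {
            f"S{i}": make_test_species(code=f"S{i}", opt_mat=o) for i, o in enumerate(optima)
        }

    def test_plants_four_of_six_viable_split_equally(self):
        pool = self._pool([5.8, 6.1, 5.5, 6.4, 5.2, 6.0])  # all near climate
        plot = plot_with([])
        regenerate(plot, {"mat": 6.0, "map": 1000.0}, ViabilityModel(pool), RegenerationConfig(), 2026)
        assert len(plot.cohorts) == 4
        for c in plot.cohorts:
            assert c.density == pytest.approx(1235.0 / 4)  # 308.75 TPH each
            assert c.dbh == 0.5
            assert c.establishment_year == 2026
            assert c.establishment_climate == {"mat": 6.0, "map": 1000.0}

    def test_highest_scores_selected_first(self):
        pool = self._pool([6.0, 6.2, 8.0, 4.0, 9.0, 3.0])
        plot = plot_with([])
        regenerate(plot, {"mat": 6.0, "map": 1000.0}, ViabilityModel(pool), RegenerationConfig(), 2026)
        assert {c.species for c in plot.cohorts} == {"S0", "S1", "S2", "S3"}

    def test_single_viable_species_gets_full_density(self):
        pool = self._pool([6.0, 20.0, -10.0])
        plot = plot_with([])
        regenerate(plot, {"mat": 6.0, "map": 1000.0}, ViabilityModel(pool), RegenerationConfig(), 2026)
        assert len(plot.cohorts) == 1
        assert plot.cohorts[0].species == "S0"
        assert plot.cohorts[0].density == pytest.approx(1235.0)

    def test_never_plants_below_threshold(self):
        pool = self._pool([20.0, -10.0])  # nothing viable at MAT 6
        plot = plot_with([])
        regenerate(plot, {"mat": 6.0, "map": 1000.0}, ViabilityModel(pool), RegenerationConfig(), 2026)
        assert plot.cohorts == []

    def test_tie_broken_by_species_code(self):
        pool = self._pool([6.5, 5.5, 6.5, 5.5, 6.5])  # 5 species, equal scores
        plot = plot_with([])
        regenerate(plot, {"mat": 6.0, "map": 1000.0}, ViabilityModel(pool), RegenerationConfig(), 2026)
        assert sorted(c.species for c in plot.cohorts) == ["S0", "S1", "S2", "S3"]


class TestAgeSnags:
    def _plot(self):
        from standclim import SnagRecord

        p = plot_with([])
        p.snags = [SnagRecord("A", 100.0, 30.0, 25.0, 2026)]
        return p

    def test_full_retention_keeps_pool(self):
        plot = self._plot()
        age_snags(plot, 1.0)
        assert plot.snags[0].density == 100.0

    def test_zero_retention_empties_pool(self):
        plot = self._plot()
        age_snags(plot, 0.0)
        assert plot.snags == []

    def test_two_cycles_compound(self):
        plot = self._plot()
        age_snags(plot, 0.7)
        age_snags(plot, 0.7)
        assert plot.snags[0].density == pytest.approx(49.0)
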