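"""Generators: species pools, landscapes, remeasurements, climate scenarios."""

import numpy as np
import pytest
from scipy import stats

from standclim import (
    ViabilityModel,
    estimate_regime,
    make_climate_scenario,
    make_landscape,
    make_remeasurement_data,
    make_species_pool,
    viability,
)
from standclim.synthetic_data import (
    DEFAULT_MAGNITUDES,
    DEFAULT_WARMING_DELTA,
    MagnitudeDistribution,
)

RANGE = {"mat": (2.0, 12.0), "map": (600.0, 1500.0)}


class TestSpeciesPool:
    def test_optima_span_range(self):
        pool = make_species_pool(6, RANGE, seed=1)
        opts = sorted(sp.optimum["mat"] for sp in pool.values())
        spacing = (12.0 - 2.0) / 5
        assert opts[0] == pytest.approx(2.0, abs=0.2 * spacing)
        assert opts[-1] == pytest.approx(12.0, abs=0.2 * spacing)
        gaps = np.diff(opts)
        assert np.all(gaps > 0.5 * spacing) and np.all(gaps < 1.5 * spacing)

    def test_same_seed_identical_pool(self):
        a = make_species_pool(5, RANGE, seed=9)
        b = make_species_pool(5, RANGE, seed=9)
        assert a == b

    def test_transect_always_covered_by_some_species(self):
        # every climate on the elevational transect has at least one
        # species with viability >= 0.5 (exhaustive grid check)
        pool = make_species_pool(6, RANGE, seed=3)
        mats = np.linspace(*RANGE["mat"], 201)
        # the paired transect: warm <-> dry under the default gradient
        fracs = (mats - RANGE["mat"][0]) / (RANGE["mat"][1] - RANGE["mat"][0])
        maps = RANGE["map"][1] - fracs * (RANGE["map"][1] - RANGE["map"][0])
        for mat, mapp in zip(mats, maps):
            best = max(
                viability(sp, {"mat": mat, "map": mapp}) for sp in pool.values()
            )
            assert best >= 0.5

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            make_species_pool(1, RANGE, seed=0)


class TestLandscape:
    def test_construction_constraints(self):
        inventory, normals = make_landscape(100, seed=4)
        assert len(inventory.plots) == 100
        vm = ViabilityModel(inventory.species_pool)
        for plot in inventory.plots:
            climate = dict(zip(["mat", "map"], normals[plot.id]))
            for cohort in plot.cohorts:
                assert vm.score(cohort.species, climate) >= 0.5

    def test_reserved_fraction(self):
        inventory, _ = make_landscape(100, seed=4, reserved_fraction=0.34)
        n_reserved = sum(p.reserved for p in inventory.plots)
        assert n_reserved == 34

    def test_reference_elevation_recovers_base_climate(self):
        inventory, normals = make_landscape(
            50, elevation_range=(999.0, 1001.0), seed=1
        )
        # at (essentially) the reference elevation, normals equal the base
        for plot in inventory.plots:
            mat, mapp = normals[plot.id]
            assert mat == pytest.approx(6.0, abs=0.01)
            assert mapp == pytest.approx(1000.0, abs=1.0)

    def test_every_plot_has_a_viable_species(self):
        inventory, normals = make_landscape(80, seed=12)
        vm = ViabilityModel(inventory.species_pool)
        for plot in inventory.plots:
            climate = dict(zip(["mat", "map"], normals[plot.id]))
            best = max(vm.score(c, climate) for c in inventory.species_pool)
            assert best >= 0.5

    def test_deterministic_under_seed(self):
        a, na = make_landscape(20, seed=7)
        b, nb = make_landscape(20, seed=7)
        for pa, pb in zip(a.plots, b.plots):
            assert pa.elevation == pb.elevation
            assert [c.dbh for c in pa.cohorts] == [c.dbh for c in pb.cohorts]
        for pid in na:
            assert np.array_equal(na[pid], nb[pid])

    def test_empty_elevation_range_rejected(self):
        with pytest.raises(ValueError):
            make_landscape(10, elevation_range=(1000.0, 1000.0))


class TestRemeasurementGenerator:
    def test_all_zero_probabilities_give_only_none_records(self):
        table = make_remeasurement_data(
            {"harvest": 0.0, "fire": 0.0, "stress": 0.0}, None, 200, seed=1
        )
        assert set(table.records["disturbance_class"]) == {"none"}

    def test_empirical_proportion_within_three_se(self):
        # Payette-style fire probability
        p = 0.144
        n = 10_000
        table = make_remeasurement_data({"fire": p}, None, n, seed=2)
        hits = table.of_class("fire")["plot_id"].nunique()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_harvest_magnitudes_always_positive(self):
        # harvesting by definition removes trees
        table = make_remeasurement_data({"harvest": 0.5}, None, 5000, seed=3)
        assert (table.of_class("harvest")["prop_ba_killed"] > 0).all()

    def test_stress_zero_kill_fraction(self):
        # about 40% of stress events kill nothing
        table = make_remeasurement_data({"stress": 1.0}, None, 5000, seed=4)
        frac_zero = (table.of_class("stress")["prop_ba_killed"] == 0).mean()
        assert frac_zero == pytest.approx(0.40, abs=0.03)

    def test_estimator_recovers_truth_with_binomial_coverage(self):
        # 30 independent datasets; the estimate must fall in the binomial
        # acceptance region of the truth in >= 90% of them, per class
        truth = {"harvest": 0.132, "fire": 0.093, "stress": 0.335}
        n = 343
        inside = {cls: 0 for cls in truth}
        n_sets = 30
        for k in range(n_sets):
            table = make_remeasurement_data(truth, None, n, seed=100 + k)
            regime = estimate_regime(table)
            for cls, p in truth.items():
                lo = stats.binom.ppf(0.025, n, p) / n
                hi = stats.binom.ppf(0.975, n, p) / n
                if lo <= regime.probabilities[cls] <= hi:
                    inside[cls] += 1
        for cls in truth:
            assert inside[cls] >= 0.9 * n_sets

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            make_remeasurement_data({"fire": 1.5}, None, 10, seed=0)


class TestMagnitudeDistribution:
    def test_atoms(self, rng):
        dist = MagnitudeDistribution(zero_prob=0.3, one_prob=0.1)
        draws = np.array([dist.sample(rng) for _ in range(5000)])
        assert (draws == 0).mean() == pytest.approx(0.3, abs=0.03)
        assert (draws == 1).mean() == pytest.approx(0.1, abs=0.02)
        mid = draws[(draws > 0) & (draws < 1)]
        assert ((mid > 0) & (mid < 1)).all()

    def test_inconsistent_atoms_rejected(self):
        with pytest.raises(ValueError):
            MagnitudeDistribution(zero_prob=0.7, one_prob=0.5)


class TestClimateScenario:
    def _normals(self):
        _, normals = make_landscape(5, seed=6)
        return normals

    def test_constant_shape_reproduces_normals(self):
        normals = self._normals()
        traj = make_climate_scenario(normals, shape="constant")
        for pid, base in normals.items():
            assert np.allclose(traj.values[pid], base[None, :])

    def test_linear_midpoint(self):
        normals = self._normals()
        traj = make_climate_scenario(normals, {"mat": 3.0, "map": 0.0}, "linear")
        pid = next(iter(normals))
        mid = traj.at(pid, 2066)  # year 50 of 100
        assert mid["mat"] == pytest.approx(normals[pid][0] + 1.5)

    def test_default_warming_within_rcp6_range(self):
        assert 1.4 <= DEFAULT_WARMING_DELTA["mat"] <= 3.1

    def test_warming_shapes_reach_delta_and_are_monotone(self):
        normals = self._normals()
        for shape in ("linear", "logistic"):
            traj = make_climate_scenario(normals, {"mat": 2.2, "map": 50.0}, shape)
            for pid, base in normals.items():
                series = traj.values[pid][:, 0]
                assert series[0] == pytest.approx(base[0])
                assert series[-1] == pytest.approx(base[0] + 2.2)
                assert np.all(np.diff(series) >= 0)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            make_climate_scenario(self._normals(), shape="cubic")
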