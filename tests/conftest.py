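import numpy as np
import pytest

from standclim import (
    ClimateGradient,
    ForestProjectionModel,
    Plot,
    SpeciesParams,
    TreeCohort,
)


def make_test_species(
    code="PINE",
    opt_mat=6.0,
    breadth_mat=2.0,
    opt_map=1000.0,
    breadth_map=400.0,
    **kw,
):
    defaults = dict(
        max_dbh=90.0,
        max_increment=0.5,
        height_k=0.03,
        height_cap=45.0,
        wood_density=450.0,
        crown_factor=1.2,
        base_max_sdi=900.0,
    )
    defaults.update(kw)
    return SpeciesParams(
        code=code,
        optimum={"mat": opt_mat, "map": opt_map},
        breadth={"mat": breadth_mat, "map": breadth_map},
        **defaults,
    )


@pytest.fixture
def species():
    return make_test_species()

@pytest.fixture
def species_pool(species):
    fir = make_test_species(code="FIR", opt_mat=3.0, base_max_sdi=700.0)
    return {"PINE": species, "FIR": fir}


@pytest.fixture
def simple_plot(species_pool):
    return Plot(
        id="P1",
        elevation=1000.0,
        reserved=False,
        expansion_factor=2400.0,
        cohorts=[
            TreeCohort("PINE", 300.0, 30.0, 25.0, 2016, {"mat": 6.0, "map": 1000.0}),
            TreeCohort("FIR", 150.0, 20.0, 18.0, 2016, {"mat": 6.0, "map": 1000.0}),
        ],
    )


@pytest.fixture(scope="session")
def small_model():
    """A 20-plot synthetic landscape with its fitted results (shared)."""
    model = ForestProjectionModel.from_synthetic(n_plots=20, seed=11)
    return model


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
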