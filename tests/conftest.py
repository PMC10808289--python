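import numpy as np
import pandas as pd
import pytest

import altidiv as ad


@pytest.fixture(scope="session")
def cfg():
    return ad.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def census_tables(cfg):
    return ad.simulate_census(cfg)


@pytest.fixture(scope="session")
def census_data(census_tables):
    census, species, plots = census_tables
    return ad.read_census(census, species, plots)


@pytest.fixture(scope="session")
def matrix(census_data):
    return ad.build_matrix(census_data)


@pytest.fixture(scope="session")
def climate_series(cfg):
    return ad.simulate_climate(cfg)


@pytest.fixture
def tiny_tables():
    """Hand-built two-plot census for exact assertions."""
    census = pd.DataFrame({
        "plot_id": ["A", "A", "A", "B", "B"],
        "species_id": ["sp1", "sp1", "sp1", "sp2", "sp2"],
        "dbh_cm": [20.0, 25.0, 30.0, 15.0, 40.0],
    })
    species = pd.DataFrame({
        "species_id": ["sp1", "sp2"],
        "family": ["f1", "f2"],
        "genus": ["g1", "g2"],
        "endemism": ["endemic", "native"],
        "status": ["LC", "EN"],
    })
    plots = pd.DataFrame({
        "plot_id": ["A", "B"],
        "altitude_m": [100.0, 1500.0],
        "area_ha": [1.0, 2.0],
        "disturbance": ["low", "high"],
    })
    return census, species, plots
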