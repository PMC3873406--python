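import numpy as np
import pandas as pd
import pytest

from invasion_hotspots.grid import GridSpec
from invasion_hotspots.occurrences import OccurrenceSet
from invasion_hotspots.synth import (
    SyntheticSpeciesSpec,
    SyntheticWorldSpec,
    generate_climate,
    generate_regions,
    generate_species,
)


@pytest.fixture(scope="session")
def world():
    """A mid-sized noisy synthetic world shared across tests."""
    return generate_climate(SyntheticWorldSpec(grid_rows=40, grid_cols=40, seed=7))


@pytest.fixture(scope="session")
def small_world():
    return generate_climate(SyntheticWorldSpec(grid_rows=20, grid_cols=20, seed=3))


@pytest.fixture(scope="session")
def species_spec():
    return SyntheticSpeciesSpec(
        species_id="testsp",
        niche_optimum=(12.0, 900.0),
        niche_breadth=(3.0, 250.0),
        n_presences=200,
    )


@pytest.fixture(scope="session")
def species_data(world, species_spec):
    return generate_species(world, species_spec, seed=11)


@pytest.fixture(scope="session")
def zones(world):
    _, z = generate_regions(world, 5, seed=7)
    return z


@pytest.fixture(scope="session")
def regions(world):
    r, _ = generate_regions(world, 5, seed=7)
    return r


def make_occurrences(species="sp", lons=None, lats=None, cultivated=None):
    n = len(lons)
    df = pd.DataFrame(
        {
            "lon": np.asarray(lons, float),
            "lat": np.asarray(lats, float),
            "cultivated": np.zeros(n, dtype=int) if cultivated is None else cultivated,
            "source": "test",
        }
    )
    return OccurrenceSet(species, df)


@pytest.fixture
def toy_grid():
    return GridSpec(rows=6, cols=6, origin_lon=0.0, origin_lat=3.0, cell_size_deg=0.5)
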