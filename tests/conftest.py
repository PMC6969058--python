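import numpy as np
import pandas as pd
import pytest

from thermovuln.grids import GridField
from thermovuln.schema import Trait, TraitSchema, default_schema
from thermovuln.synth import SynthConfig, simulate
from thermovuln.trees import Phylogeny


@pytest.fixture(scope="session")
def schema16():
    """The built-in 16-trait schema (15 sensitivity / 13 functional)."""
    return default_schema()


@pytest.fixture
def two_trait_schema():
    return TraitSchema(traits=(
        Trait("depth", "habitat", "quantitative", use_functional=False),
        Trait("vertical", "habitat", "qualitative",
              {"epipelagic": 2, "benthic": 1, "mesopelagic": 1, "generalist": 0},
              use_functional=False),
    ))


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete synthetic study shared across tests."""
    cfg = SynthConfig(
        n_species=15, seed=11,
        lat_min=-40, lat_max=40, lon_min=-40, lon_max=40,
        n_models=3, n_trees=5,
        range_size_min=5, range_size_max=150,
        iucn_counts={"CR": 1, "EN": 2, "VU": 2, "NT": 1, "LC": 8, "DD": 1},
    )
    return simulate(cfg)


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); total branch length 5."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


def make_field(values, mask=None, lat0=0.5, lon0=0.5):
    """Small helper: a GridField from a 2-D array at 1-degree spacing."""
    values = np.asarray(values, float)
    nlat, nlon = values.shape
    lat = lat0 + np.arange(nlat)
    lon = lon0 + np.arange(nlon)
    if mask is None:
        mask = np.ones_like(values, bool)
    return GridField(lat=lat, lon=lon, values=values, mask=np.asarray(mask, bool))
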