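import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gillnet import (FeatureTable, PhyloTree, SampleMetadata, TaxonomyMap)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def toy_table() -> FeatureTable:
    data = pd.DataFrame(
        [[5, 0, 3, 1], [2, 4, 0, 6], [1, 1, 1, 1], [0, 7, 2, 0]],
        index=["asvA", "asvB", "asvC", "asvD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    df = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P2", "P2"],
            "genus": ["Ga", "Ga", "Gb", ""],
        },
        index=["asvA", "asvB", "asvC", "asvD"],
    )
    return TaxonomyMap(df)


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "community": ["north", "north", "south", "south"],
            "water_type": ["Freshwater", "Freshwater", "Saltwater", "Saltwater"],
            "latitude": [69.1, 69.2, 58.5, 58.6],
            "air_temperature": [-2.0, -1.5, 7.0, 7.5],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleMetadata(df)


@pytest.fixture
def toy_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "((asvA:0.5,asvB:0.5):0.25,(asvC:0.4,asvD:0.6):0.35);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
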