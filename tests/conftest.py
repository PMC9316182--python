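import warnings

import pytest

from rfmap import synthetic_data
from rfmap.core import F2Plant, GenotypeCall, MarkerDef, Phenotype


@pytest.fixture(scope="session")
def table2_records():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic_data.load_fixture("table2_families")


@pytest.fixture(scope="session")
def table3_primary():
    return synthetic_data.load_fixture("table3_primary")


@pytest.fixture(scope="session")
def table3_fine():
    return synthetic_data.load_fixture("table3_fine")


@pytest.fixture(scope="session")
def table4_genes():
    return synthetic_data.load_fixture("table4_genes")


@pytest.fixture(scope="session")
def table5_matrix():
    return synthetic_data.load_fixture("table5_matrix")


def make_plant(plant_id, phenotype, symbols, marker_names):
    """Build an F2Plant from one-letter genotype symbols."""
    calls = {m: GenotypeCall.from_symbol(s) for m, s in zip(marker_names, symbols)}
    return F2Plant(plant_id, phenotype, calls)


@pytest.fixture
def tiny_population():
    markers = ["m1", "m2"]
    plants = [
        make_plant("p1", Phenotype.FERTILE, "AH", markers),
        make_plant("p2", Phenotype.STERILE, "HB", markers),
        make_plant("p3", Phenotype.FERTILE, "B-", markers),
    ]
    return plants, markers


@pytest.fixture
def marker_factory():
    def factory(name="m", position=1, chromosome="Chr06"):
        return MarkerDef(name, chromosome, position)

    return factory
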