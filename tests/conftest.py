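import numpy as np
import pytest

from cbfsurvey import synthetic_data as sd


@pytest.fixture(scope="session")
def default_spec() -> sd.FixtureSpec:
    return sd.FixtureSpec(seed=20191017)


@pytest.fixture(scope="session")
def genome_fixture(default_spec):
    return sd.make_genome(default_spec)


@pytest.fixture(scope="session")
def counts_fixture(default_spec, genome_fixture):
    return sd.make_counts(default_spec, [g.gene_id for g in genome_fixture.genes])


@pytest.fixture(scope="session")
def family_fixture(default_spec):
    return sd.make_family(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
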