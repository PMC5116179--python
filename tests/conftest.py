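import numpy as np
import pytest

from rarecase import synthetic_data, variant_io
from rarecase.trio_filters import FilterThresholds


@pytest.fixture
def thresholds():
    return FilterThresholds()


@pytest.fixture
def table1():
    return variant_io.build_fixture("table1")


@pytest.fixture
def table2():
    return variant_io.build_fixture("table2")


@pytest.fixture
def table3():
    return variant_io.build_fixture("table3")


@pytest.fixture
def combined_records():
    return variant_io.combined_fixture_records()


@pytest.fixture
def sim_config():
    rng = np.random.default_rng(12345)
    planted = synthetic_data.plant_default_variants(10, rng)
    return synthetic_data.SimConfig(
        seed=12345,
        planted=planted,
        n_background_variants=200,
        cna_truth=synthetic_data.default_cna_truth(),
    )
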