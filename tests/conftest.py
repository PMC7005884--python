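import pytest

from sipcell.simulate import gom_fixture, simulate_dataset


@pytest.fixture(scope="session")
def small_scenario():
    cfg = gom_fixture(seed=42)
    cfg.nanosims.cells_per_taxon = 15
    cfg.nanosims.planes = 10
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    directory = tmp_path_factory.mktemp("dataset")
    small_dataset.write(directory)
    return directory
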