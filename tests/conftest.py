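import pytest

from its2delim.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_cfg):
    """Default synthetic dataset (2 lineages x 3 clades x 4 strains, seed 1)."""
    records, truth = simulate(sim_cfg)
    return records, truth


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    from its2delim.pipeline import analyze

    records, _truth = dataset
    return analyze(records)
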