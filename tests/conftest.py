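import numpy as np
import pytest

from gpovae import (
    SimulationConfig,
    build_dge_reference,
    sample_ground_truth_grn,
    simulate_perturbseq,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_perturbed=6,
        n_extended=4,
        n_other_genes=10,
        cells_per_treatment=40,
        n_control=40,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    grn = sample_ground_truth_grn(small_config)
    dataset, _ = simulate_perturbseq(grn, small_config)
    return small_config, grn, dataset


@pytest.fixture(scope="session")
def small_dge(small_sim):
    _, _, dataset = small_sim
    return build_dge_reference(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
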