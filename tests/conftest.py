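import numpy as np
import pytest

from svcmix import SamplerConfig, SpatialMixtureModel, generate_dataset, scenario_spec
from svcmix.simulate import dataset_seeds


@pytest.fixture(scope="session")
def one_dim_sim():
    """One small simulated dataset with the one-dimensional effect surface."""
    spec = scenario_spec("one_dim", n=150, n_datasets=1, seed=7)
    return generate_dataset(spec, int(dataset_seeds(spec)[0]))


@pytest.fixture(scope="session")
def small_fit(one_dim_sim):
    """A short two-chain fit of the small one_dim dataset, shared across tests."""
    model = SpatialMixtureModel(one_dim_sim.dataset)
    config = SamplerConfig(n_chains=2, burn_in=300, retained=300, seed=42, progress_every=0)
    return model.fit(config)
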