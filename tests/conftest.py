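import numpy as np
import pytest

from grkin.models import build_model
from grkin.synthetic import SyntheticConfig, generate_dataset, sample_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_params(model_id, seed=0):
    """Well-behaved random interior rates for one topology."""
    return sample_parameters(build_model(model_id), np.random.default_rng(seed))


def make_dataset(model_id, seed=0, noise_cv=0.0, times=(0.0, 2.0, 10.0), n_replicates=3):
    """Synthetic dataset plus its generating truth."""
    params = sample_parameters(build_model(model_id), np.random.default_rng(seed))
    return generate_dataset(SyntheticConfig(
        model_id, params, times=times, n_replicates=n_replicates,
        noise_cv=noise_cv, seed=seed))
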