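import numpy as np
import pytest

from fiberopt.preprocessing import preprocess_pipeline
from fiberopt.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def marginal_ds():
    """A mid-sized marginal-mode dataset with the default 126 missing cells."""
    ds, truth = generate_dataset(SyntheticConfig(n_rows=200, seed=7, mode="marginal"))
    return ds, truth


@pytest.fixture(scope="session")
def surface_ds():
    """A noiseless surface-mode dataset (no missing cells): labels are an
    exact deterministic function of the features."""
    cfg = SyntheticConfig(
        n_rows=500, seed=11, mode="surface", n_missing=0, noise_scale=0.0
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def surface_pre(surface_ds):
    ds, truth = surface_ds
    return preprocess_pipeline(ds), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
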