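import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact planted bundle shared by integration-level tests."""
    from crossmut.synthetic import SyntheticConfig, generate_bundle

    return generate_bundle(SyntheticConfig(n_genes=120, n_tissues=12, seed=7,
                                           cohort_size=100))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_freqs():
    return pd.Series([0.00, 0.01, 0.50, 0.60], index=["t1", "t2", "t3", "t4"])
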