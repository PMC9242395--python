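import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_experiment():
    """A 2-pair experiment shared by structural tests (cheap to generate)."""
    from tapsync.synth import ExperimentDesign, generate_experiment

    return generate_experiment(ExperimentDesign(n_pairs=2, seed=99))
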