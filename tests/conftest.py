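import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free, paralog-free simulated data set with truth."""
    from grasspanel.simulate import SimConfig, simulate_reads, simulate_reference

    cfg = SimConfig(
        n_unigenes=30,
        mean_unigene_len=400,
        depth=20,
        base_error=0.0,
        paralog_fraction=0.0,
        inbred_residual_het=0.0,
        pop_size=60,
        seed=42,
    )
    unigenes, truth = simulate_reference(cfg)
    reads = simulate_reads(unigenes, truth, cfg)
    return cfg, unigenes, truth, reads


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
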