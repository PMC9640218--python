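import numpy as np
import pytest

from ripplemap import SimSpec, simulate_bundle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """A short multimodal session used by io / pipeline tests."""
    spec = SimSpec(duration_s=120.0, n_cells=60, n_assemblies=2,
                   assembly_size_range=(15, 25), swr_rate_hz=0.3,
                   rng_seed=42)
    return simulate_bundle(spec)


@pytest.fixture(scope="session")
def medium_session():
    """A 600 s default-amplitude session with all modalities."""
    spec = SimSpec(duration_s=600.0, n_cells=200, n_assemblies=4,
                   assembly_size_range=(30, 45), rng_seed=7)
    return simulate_bundle(spec)
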