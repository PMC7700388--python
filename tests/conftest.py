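import numpy as np
import pytest

from memorient import (SyntheticSpec, build_protein_template,
                       generate_trajectory)
from memorient.io_core import DEFAULT_SELECTION_CONFIG


@pytest.fixture(scope="session")
def template():
    return build_protein_template()


@pytest.fixture(scope="session")
def selections():
    return dict(DEFAULT_SELECTION_CONFIG)


@pytest.fixture(scope="session")
def noise_free_run():
    """Tiny deterministic trajectory with zero noise: every recovered
    quantity must equal its ground-truth target exactly (to float precision)."""
    spec = SyntheticSpec(n_frames=10, positional_jitter_sigma=0.0,
                         sigma_angle=0.0, theta=80.0, phi=105.0,
                         depth_far=1.73, depth_gtp=4.38, seed=11)
    frames, truth = generate_trajectory(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def jittered_run():
    """Moderately noisy run used by statistical-recovery tests."""
    spec = SyntheticSpec(n_frames=120, positional_jitter_sigma=0.05,
                         sigma_angle=6.0, theta=80.0, phi=105.0,
                         depth_far=1.73, depth_gtp=4.38, seed=7)
    frames, truth = generate_trajectory(spec)
    return spec, frames, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
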