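import numpy as np
import pytest

from limbloci import simulate as sim


@pytest.fixture(scope="session")
def mask():
    return sim.make_pcl_mask()


@pytest.fixture(scope="session")
def quiet_config():
    """Noiseless, driftless, motionless conditions for exactness checks."""
    return sim.SimConfig(
        noise_sd=0.0,
        drift_scale=0.0,
        spike_prob=0.0,
        motion_walk_sd=0.0,
        dtype="float64",
        seed=0,
    )


@pytest.fixture(scope="session")
def quiet_truth(mask, quiet_config):
    return sim.make_ground_truth(mask, quiet_config)
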