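import numpy as np
import pytest

from axoprop import SimulationConfig, build_default_layout


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture
def clean_single_axon_config():
    """One axon per channel, no jitter, perfect detection: exact recovery."""
    return SimulationConfig(
        duration_s=30.0, tonic_rate_hz=2.0, burst_rate_hz=0.1,
        n_axons_per_channel=1, true_velocity_m_s=0.5,
        jitter_ms=0.0, detection_prob=1.0, seed=42,
    )
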