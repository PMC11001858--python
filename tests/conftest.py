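import pandas as pd
import pytest

import willisflow as wf


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free default (compliant) generator configuration."""
    return wf.default_config(noise_sd_flow=0.0, noise_sd_pressure=0.0)


@pytest.fixture(scope="session")
def clean_set(clean_config):
    """Noise-free synthetic 10-vessel dataset, 3 cycles at 1 kHz."""
    return wf.generate_waveform_set(clean_config)


@pytest.fixture(scope="session")
def noisy_set():
    """Default synthetic dataset with sensor noise at the default SDs."""
    return wf.generate_waveform_set(wf.default_config())


@pytest.fixture(scope="session")
def cow_net():
    """Complete Circle-of-Willis network from the synthetic geometry."""
    return wf.build_network(wf.synthetic_cow_geometry())


@pytest.fixture()
def y_network():
    """1 inlet feeding two identical branches to two outlets."""
    geo = pd.DataFrame(
        [
            ("IN", "LICA", "J", 50.0, 4.0),
            ("B1", "J", "LACA", 30.0, 2.0),
            ("B2", "J", "RACA", 30.0, 2.0),
        ],
        columns=["segment", "node_a", "node_b", "length_mm", "diameter_mm"],
    )
    return wf.build_network(geo, inlets=["LICA"], outlets=["LACA", "RACA"])
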