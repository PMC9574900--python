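import numpy as np
import pytest
from hypothesis import settings

import ctnet

# derandomized hypothesis profile so runs are reproducible
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default alpha-regime parameter set."""
    return ctnet.CorticothalamicParams()


@pytest.fixture(scope="session")
def fast_params(params):
    """Short-duration variant for cheap simulation tests."""
    return params.replace(duration=6.0, transient=1.0)


@pytest.fixture(scope="session")
def small_connectome():
    """Small synthetic network to keep simulation tests cheap."""
    cfg = ctnet.ConnectomeSimConfig(n_regions=12, edge_density=0.4, seed=7)
    return ctnet.generate_connectome(cfg).replace(global_coupling=5e-5)


@pytest.fixture(scope="session")
def connectome78():
    """Full-size synthetic connectome at the default coupling gain."""
    cfg = ctnet.ConnectomeSimConfig(seed=42)
    return ctnet.generate_connectome(cfg).replace(global_coupling=5e-5)


def sine_result(freq_hz, fs=250.0, duration=20.0, n_regions=1, amp=1.0,
                phase=0.0, noise=0.0, seed=0):
    """Synthetic SimulationResult holding sinusoidal test signals."""
    t = np.arange(int(duration * fs)) / fs
    rng = np.random.default_rng(seed)
    series = np.vstack([
        amp * np.sin(2 * np.pi * freq_hz * t + phase)
        + noise * rng.standard_normal(t.size)
        for _ in range(n_regions)
    ])
    return ctnet.SimulationResult(series=series, fs=fs, seed=seed,
                                  params_hash="synthetic")
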