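import numpy as np
import pytest

from islet3d import SyntheticConfig, generate_islet, segment_dataset


def small_config(**overrides) -> SyntheticConfig:
    """A fast, fully featured islet: 60 cells, 3 oscillations, 2 Hz."""
    params = dict(
        n_cells=60,
        islet_radius=35.0,
        period=100.0,
        duty_cycle=0.45,
        rise_time=4.0,
        n_oscillations=3,
        sampling_rate=2.0,
        wave_speed=10.0,
        seed=11,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def noisy_islet():
    return generate_islet(small_config())


@pytest.fixture(scope="session")
def noiseless_islet():
    return generate_islet(small_config().noiseless())


@pytest.fixture(scope="session")
def noiseless_segments(noiseless_islet):
    dataset, _ = noiseless_islet
    segments, table = segment_dataset(dataset, min_separation=50.0)
    return segments, table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
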