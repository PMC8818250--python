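import numpy as np
import pytest
from hypothesis import settings

from platescreen import (
    ArrayFormat,
    NormalizationOptions,
    SimulationConfig,
    calculate_lgrs,
    simulate_screen,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fmt96():
    return ArrayFormat.from_total(96)


@pytest.fixture(scope="session")
def fmt384():
    return ArrayFormat.from_total(384)


@pytest.fixture(scope="session")
def fmt1536():
    return ArrayFormat.from_total(1536)


def make_noiseless_config(fmt, n_plates=1, replicates=4, planted=None, **kw):
    """A deterministic screen: no noise, no plate effects, no edge, no failures."""
    defaults = dict(
        format=fmt,
        n_plates=n_plates,
        replicates=replicates,
        noise_sigma=0.0,
        plate_effect_sigma=0.0,
        edge_amplitude=0.0,
        pinning_failure_rate=0.0,
        n_controls=1,
        planted_effects=planted or {},
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_noisy_screen(fmt384):
    """A 2-plate noisy screen with 12 planted growth defects, shared across tests."""
    config = SimulationConfig(
        format=fmt384,
        n_plates=2,
        replicates=4,
        noise_sigma=0.1,
        plate_effect_sigma=0.1,
        edge_amplitude=0.3,
        pinning_failure_rate=0.01,
        n_controls=2,
        planted_effects={f"HIT{i:02d}": 0.8 for i in range(1, 13)},
        seed=11,
    )
    return simulate_screen(config)


@pytest.fixture(scope="session")
def small_noisy_results(small_noisy_screen):
    opts = NormalizationOptions(smooth=True)
    rep1, mean1 = calculate_lgrs(
        small_noisy_screen.experiment, small_noisy_screen.controls[0],
        small_noisy_screen.key, opts,
    )
    rep2, mean2 = calculate_lgrs(
        small_noisy_screen.experiment, small_noisy_screen.controls[1],
        small_noisy_screen.key, opts,
    )
    return rep1, mean1, rep2, mean2
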