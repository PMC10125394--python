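import numpy as np
import pytest

from fixir.core import DEFAULT_BANDS, BandModel, StudyConfig, WavenumberGrid


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_config():
    """Noise-free generator settings (expectation == band sum)."""
    return StudyConfig(noise_sd=0.0, baseline_scale=0.0, atmospheric_scale=0.0)


@pytest.fixture
def small_config():
    """Small but noisy study for fast integration tests."""
    return StudyConfig(
        tissues_per_time=2,
        replicates_per_tissue=2,
        regions_per_slide=5,
        seed=11,
    )


@pytest.fixture
def single_amide_band():
    return [BandModel(1626.0, center_shift=8.0, width0=22.0, width_gain=0.0,
                      amp0=1.0, tau=4.0, name="amide_i")]
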