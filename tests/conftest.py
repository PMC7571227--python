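import numpy as np
import pytest

from ldvbeat import SyntheticConfig, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, drift-free, single-pulse simulator settings."""
    return SyntheticConfig(
        duration_s=12.0,
        hr_mean_bpm=60.0,
        hr_sd_bpm=0.0,
        noise_sd=0.0,
        resp_amp=0.0,
        jugular_amp_frac=0.0,
        pulse_delay_sd_ms=0.0,
        pulse_width_sd_ms=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_recording(clean_config)


@pytest.fixture(scope="session")
def default_recording():
    """One minute under the default (moderate-noise) study conditions."""
    return generate_recording(SyntheticConfig(duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Four 30-second subjects under default conditions."""
    return generate_cohort(
        4, SyntheticConfig(duration_s=30.0), subject_jitter=0.1, seed=5
    )
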