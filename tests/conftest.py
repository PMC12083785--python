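import numpy as np
import pytest

from apneagram.config import RunConfig
from apneagram.synth import SynthConfig, generate_study


def clean_synth_config(**kw) -> SynthConfig:
    """Artifact-free generator settings for focused unit tests."""
    base = dict(
        duration_h=0.25, target_ahi=0.0, wake_initial_s=0.0, wake_final_s=0.0,
        n_awakenings=0, ectopic_rate_per_h=0.0, n_saturation=0, n_noise_bursts=0,
        snr_db=None, mains_amp_mv=0.0, wander_amp_mv=0.0, seed=11,
    )
    base.update(kw)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def clean_study():
    """15 min artifact-free sinus-rhythm study."""
    return generate_study(clean_synth_config())


@pytest.fixture(scope="session")
def noisy_event_study():
    """1 h study with events, ectopics and artifacts at the default SNR."""
    return generate_study(
        SynthConfig(duration_h=1.0, target_ahi=30.0, frac_hypopnea=0.2,
                    frac_central=0.1, wake_initial_s=0.0, wake_final_s=0.0,
                    n_awakenings=0, seed=21)
    )


@pytest.fixture()
def short_run_config() -> RunConfig:
    """Pipeline config with the analyzability gate scaled to short fixtures."""
    cfg = RunConfig()
    cfg.rhythm.min_hours = 0.1
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
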