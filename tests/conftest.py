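import numpy as np
import pytest

from respiradar import RadarConfig, SubjectProfile, TrialSchedule


@pytest.fixture()
def config() -> RadarConfig:
    return RadarConfig()


def noiseless_profile(**overrides) -> SubjectProfile:
    """A subject with all stochastic components switched off."""
    params = dict(
        motion_noise_sd=0.0,
        phase_noise_sd=0.0,
        period_variability=0.0,
        amplitude_variability=0.0,
    )
    params.update(overrides)
    return SubjectProfile(**params)


def sine_window(period_s: float = 4.0, amplitude: float = 1.0,
                n: int = 400, dt: float = 0.01, phase: float = 0.0
                ) -> np.ndarray:
    t = dt * np.arange(n)
    return amplitude * np.sin(2 * np.pi * t / period_s + phase)
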