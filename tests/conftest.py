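import numpy as np
import pytest

from leadrecon.synth import (DipoleModel, PopulationConfig, SubjectParams,
                             DEFAULT_WAVE_AMPLITUDES, generate_cohort,
                             generate_record, noise_free)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def template_subject(heart_rate: float = 60.0, rr_jitter_sd: float = 0.0,
                     noise_sd: float = 0.0, wander: float = 0.0,
                     azimuth: float = 0.0, elevation: float = 0.0,
                     global_scale: float = 1.0) -> SubjectParams:
    """A subject with textbook wave amplitudes and no variability."""
    model = DipoleModel()
    return SubjectParams(
        heart_rate=heart_rate, rr_jitter_sd=rr_jitter_sd,
        axis_azimuth=azimuth, axis_elevation=elevation,
        wave_amplitudes={w: tuple(v) for w, v in DEFAULT_WAVE_AMPLITUDES.items()},
        st_level=model.st_level, global_scale=global_scale,
        noise_sd=noise_sd, baseline_wander_amp=wander,
        baseline_wander_freq=0.25, subject_id="template")


@pytest.fixture
def template_record():
    """Noise-free, jitter-free 10 s record at 60 bpm from default amplitudes."""
    return generate_record(template_subject(), DipoleModel(), duration=10.0,
                           fs=500.0, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free 20-subject cohort (10 s records) for measurement tests."""
    return generate_cohort(20, noise_free(PopulationConfig()), seed=17)


@pytest.fixture(scope="session")
def desk_cohort():
    """Default-noise desk cohort: 40 subjects, 4 s records."""
    return generate_cohort(40, seed=17, duration=4.0)
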