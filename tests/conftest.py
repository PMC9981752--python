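import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 6+6-subject cohort with a clear rhythm, for pipeline tests."""
    from chorodiurnal.synthetic import CohortConfig, RhythmParams, generate_diurnal_cohort

    params_a = RhythmParams(
        mesor=14.0, amplitude_pt=3.0, acrophase_h=16.0,
        sd_mesor=1.0, sd_amplitude=0.5, sd_acrophase_h=1.0, noise_sd=0.3,
    )
    params_b = RhythmParams(
        mesor=13.0, amplitude_pt=2.0, acrophase_h=20.0,
        sd_mesor=1.0, sd_amplitude=0.5, sd_acrophase_h=1.0, noise_sd=0.3,
    )
    cfg = CohortConfig(
        groups={
            "myope": {("flow_deficit_density", "sub_foveal"): params_a},
            "non_myope": {("flow_deficit_density", "sub_foveal"): params_b},
        },
        n_per_group=6,
        seed=42,
    )
    return generate_diurnal_cohort(cfg)
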