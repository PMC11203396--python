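import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import iodecon as io

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_truth() -> io.GroundTruth:
    """30 genes: 4 stroma-up, 4 stroma-down, 4 cancer-specific (2 cohorts)."""
    return io.generate_ground_truth(
        30, 4, 4, 4, effect_size=1.0, noise_sd=0.2, seed=7,
        cancer_cohorts=["cohort_a", "cohort_b"],
    )


@pytest.fixture(scope="session")
def zero_noise_truth() -> io.GroundTruth:
    return io.generate_ground_truth(
        24, 3, 3, 2, effect_size=1.0, noise_sd=0.0, seed=11,
        cancer_cohorts=["cohort_a"],
    )


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise_truth) -> io.CohortData:
    cfg = io.CohortConfig(cohort_id="cohort_a", n_samples=40, cohort_class="icb",
                          responder_fraction=0.4, seed=3)
    return io.generate_cohort(zero_noise_truth, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
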