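import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radsig.synthetic import ClassEffect, SyntheticCohortConfig, generate_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def small_config(**overrides) -> SyntheticCohortConfig:
    """A reduced phantom configuration used to keep image-level tests quick."""
    defaults = dict(
        n_train=30,
        n_val=15,
        prevalence=0.4,
        grid_shape=(24, 24, 12),
        voxel_spacing=(1.0, 1.0, 2.0),
        tumor_radius_range=(8.0, 10.0),
        class_effect=ClassEffect(mean_shift=10.0, corr_length_mm=(2.0, 3.5), noise_sd=10.0),
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticCohortConfig(**defaults)


@pytest.fixture(scope="session")
def phantom():
    """One deterministic two-modality phantom (progression class)."""
    rng = np.random.default_rng(42)
    return generate_phantom(small_config(), 1, rng, "FIX01")


@pytest.fixture(scope="session")
def phantom_features(phantom):
    """The phantom's full 970-entry feature vector (computed once)."""
    from radsig.features import extract_patient

    return extract_patient(
        (phantom.volumes["CET1-w"], phantom.mask),
        (phantom.volumes["T2-w"], phantom.mask),
    )
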