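import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ivimdti as m

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: reduced phantom for Monte-Carlo style tests (~30 voxels per ROI)
SMALL_GRID = dict(
    shape=(16, 16, 6), leg_radius=3.0, injury_semiaxes=(2.0, 2.0), n_injury_slices=4
)


@pytest.fixture(scope="session")
def scheme():
    return m.default_scheme()


@pytest.fixture(scope="session")
def noise_free_study():
    """Default-size two-tissue phantom without noise."""
    return m.build_phantom(m.PhantomSpec(snr=np.inf, seed=20))


@pytest.fixture(scope="session")
def noise_free_fits(noise_free_study):
    return (
        m.pipeline_full(noise_free_study),
        m.pipeline_highb(noise_free_study),
    )


@pytest.fixture(scope="session")
def noisy_study():
    """Default-size phantom at the healthy-muscle SNR of 45."""
    return m.build_phantom(m.PhantomSpec(snr=45.0, seed=21))


@pytest.fixture(scope="session")
def noisy_fits(noisy_study):
    return (
        m.pipeline_full(noisy_study),
        m.pipeline_highb(noisy_study),
    )
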