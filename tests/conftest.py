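import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mbceus import CompressionLaw, KineticParams, make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_law():
    """Wide-dynamic-range law used by the simulator."""
    return CompressionLaw(dr_db=40.0, e_ref=2000.0)


@pytest.fixture(scope="session")
def narrow_law():
    """The narrow 7 dB display setting of targeted-contrast exams."""
    return CompressionLaw(dr_db=7.0, e_ref=100.0)


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture()
def small_phantom():
    """32x32 fully perfused disc phantom, cheap enough for many renders."""
    return make_phantom(shape=(32, 32), tumor_radius=10.0, necrotic_fraction=0.0, pad_rows=4)


@pytest.fixture(scope="session")
def time_grid():
    from mbceus.containers import clip_times
    from mbceus.synthetic_data import DEFAULT_CLIPS

    return clip_times(DEFAULT_CLIPS, 10.0)


def roi_power_curve(cine, roi, law):
    """Convenience: linearized mean ROI power per frame as ndarray."""
    from mbceus import roi_tic

    return roi_tic(cine, roi, law).values


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
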