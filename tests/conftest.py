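import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tonomap as tm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return tm.make_protocol()


@pytest.fixture(scope="session")
def half_octave_protocol():
    """Small grid with exact power-of-two frequencies for hand-checkable cases."""
    freqs = tuple(1000.0 * 2.0 ** (k / 2.0) for k in range(9))  # 1-16 kHz
    return tm.make_protocol(frequencies_hz=freqs,
                            intensities_db=(0.0, 10.0, 20.0, 30.0, 40.0),
                            n_trials=3)


def make_recording(counts, site_id="s0", pre_ms=50.0, post_ms=100.0,
                   x_um=0.0, y_um=0.0):
    return tm.SiteRecording(site_id=site_id, x_um=x_um, y_um=y_um,
                            counts=np.asarray(counts), pre_ms=pre_ms,
                            post_ms=post_ms)
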