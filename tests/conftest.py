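import numpy as np
import pytest

from psakit import optics
from psakit.synth import TraceGenConfig, gen_trace


@pytest.fixture(scope="session")
def geometry():
    return optics.EyeGeometry()


@pytest.fixture(scope="session")
def camera():
    return optics.CameraModel()


@pytest.fixture(scope="session")
def coarse_lut(geometry, camera):
    """Calibration LUT at 0.02 deg resolution — fast, adequate for most
    module tests (fine 0.001 deg grids are exercised separately)."""
    return optics.build_calibration_lut(geometry, camera, step=0.02)


@pytest.fixture(scope="session")
def clean_trace():
    """Noiseless, blink-free synthetic trial with a known artefact slope."""
    cfg = TraceGenConfig(noise_sd=0.0, blink_rate=0.0, injected_slope=-0.4,
                         injected_offset=0.25, seed=11)
    trace, truth = gen_trace(cfg)
    return trace, truth


@pytest.fixture(scope="session")
def noisy_trace():
    """Default study conditions: noise plus blinks."""
    cfg = TraceGenConfig(seed=7)
    trace, truth = gen_trace(cfg)
    return trace, truth


def uniform_pupil_trace(slope, offset=0.0, d_ref=4.0, n=20001, rate=1000.0):
    """Trace whose pupil sweeps a uniform ramp (n - 1 divisible by 20, so
    half-decile band boundaries fall on exact order statistics): the band
    means then sit at a constant offset from the deciles and the
    decile-curve fit recovers the slope exactly."""
    from psakit.signal import SignalTrace

    t = np.arange(n) / rate
    pupil = np.linspace(2.5, 5.5, n)
    dev = offset + slope * (pupil - d_ref)
    return SignalTrace(t=t, dev_h=dev, dev_v=np.zeros(n), pupil=pupil,
                       valid=np.ones(n, bool), rate=rate, pupil_unit="mm")
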