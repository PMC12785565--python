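import numpy as np
import pytest

from sockcop.geometry import CoPSeries, default_geometry


@pytest.fixture
def geometry():
    return default_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_cop(x, y, rate_hz=125.0, t0=0.0, source="sock", valid=None, **ann):
    """Build a CoPSeries from value arrays on a uniform grid."""
    x = np.asarray(x, dtype=float)
    t = t0 + np.arange(x.size) / rate_hz
    return CoPSeries(t=t, x=x, y=np.asarray(y, dtype=float), source=source,
                     valid=valid, annotations=ann)


@pytest.fixture
def smooth_signal(rng):
    """Aperiodic band-limited signal, 10 s at 125 Hz (for alignment tests)."""
    from scipy import signal as sps

    def _make(seed=None, n=1250, rate=125.0, cutoff=4.0):
        gen = np.random.default_rng(seed) if seed is not None else rng
        sos = sps.butter(4, cutoff, fs=rate, output="sos")
        x = sps.sosfiltfilt(sos, gen.standard_normal(n + 500))[250:-250]
        return x / x.std()

    return _make
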