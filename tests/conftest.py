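import numpy as np
import pytest

from gecnet.core_data import RegionalTimeSeries, StructuralConnectome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_symmetric_sc(rng):
    w = np.abs(rng.normal(0.0, 1.0, (8, 8)))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return StructuralConnectome(w)


@pytest.fixture
def sinusoid_ts():
    """Two tones (0.04 and 0.06 Hz) plus weak noise at human-like TR."""
    tr = 0.72
    t = np.arange(2000) * tr
    rng = np.random.default_rng(0)
    values = np.column_stack([
        np.sin(2 * np.pi * 0.04 * t),
        np.sin(2 * np.pi * 0.06 * t + 1.0),
    ]) + 0.01 * rng.standard_normal((t.size, 2))
    return RegionalTimeSeries(values, tr_seconds=tr)
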