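import numpy as np
import pytest

from rhythmscan.core import Regime, TimeCourseMatrix


@pytest.fixture
def times13():
    return np.arange(13) * 4.0


def make_matrix(profiles, regime=Regime.LD, n_replicates=2, probe_ids=None):
    """Matrix whose replicates are identical copies of the given profiles."""
    profiles = np.asarray(profiles, dtype=float)
    arr = np.repeat(profiles[:, :, None], n_replicates, axis=2)
    ids = probe_ids or [f"p{i}" for i in range(len(profiles))]
    return TimeCourseMatrix(probe_ids=ids, intensities=arr, regime=regime)


@pytest.fixture
def cosine_profile(times13):
    def _make(baseline=100.0, amplitude=40.0, period=24.0, peak_hr=0.0):
        return baseline + amplitude * np.cos(2 * np.pi * (times13 - peak_hr) / period)
    return _make
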