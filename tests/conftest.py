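import numpy as np
import pytest

from restdcx.containers import ROITimeSeries
from restdcx.synthetic_cohort import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 12-node, quickly simulated cohort specification."""
    return CohortSpec(
        n_nodes=12, n_sensors=32, n_controls=3, n_patients=4,
        epochs_per_subject=8, samples_per_epoch=200, seed=42,
    )


def simulate_mvar(coeffs, n_samples, n_trials, seed, burn=300):
    """Independent reference MVAR simulator used as a test signal source."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    gen = np.random.default_rng(seed)
    data = np.zeros((n, n_samples, n_trials))
    for k in range(n_trials):
        x = np.zeros((n, n_samples + burn))
        eps = gen.standard_normal((n, n_samples + burn))
        for t in range(n_samples + burn):
            acc = eps[:, t].copy()
            for r in range(1, p + 1):
                if t - r >= 0:
                    acc += coeffs[r - 1] @ x[:, t - r]
            x[:, t] = acc
        data[:, :, k] = x[:, burn:]
    return data


@pytest.fixture
def mvar_signal():
    return simulate_mvar


@pytest.fixture
def roi_from_array():
    def _make(data, fs=250.0):
        return ROITimeSeries(data=np.asarray(data, dtype=float), fs=fs)

    return _make
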