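import numpy as np
import pytest

from crossmu.simulate import CohortSpec, PoolConfig
from crossmu.types import Annotation, ForceTrace, MotorUnitTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pool():
    return PoolConfig(n_units=20, seed=7)


@pytest.fixture
def tiny_cohort_spec():
    """Scaled-down cohort for fast end-to-end tests."""
    return CohortSpec(
        n_subjects=4, hold_s=10.0, n_mup_units=2, mup_discharges=45
    )


def regular_train(rate_pps=8.0, duration_s=10.0, t0=0.0, **kw):
    times = t0 + np.arange(1, int(rate_pps * duration_s) + 1) / rate_pps
    kw.setdefault("mu_id", "mu001")
    kw.setdefault("pnr_db", 40.0)
    return MotorUnitTrain(spike_times_s=times, **kw)


def trace_from(samples, fs=1000.0, **kw):
    return ForceTrace(np.asarray(samples, float), fs, **kw)


@pytest.fixture
def trapezoid_trace():
    """Ideal trapezoid: 5 s ramp, 20 s hold at 100 N, 5 s ramp-down."""
    fs = 1000.0
    t = np.arange(int(30 * fs)) / fs
    f = np.piecewise(
        t,
        [t < 5, (t >= 5) & (t < 25), t >= 25],
        [lambda x: 20 * x, 100.0, lambda x: 100 - 20 * (x - 25)],
    )
    return ForceTrace(f, fs, target_fraction=0.25)


__all__ = ["regular_train", "trace_from", "Annotation"]
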