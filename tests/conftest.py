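import numpy as np
import pytest

from sledfriction import SimParams, SledTestConfig, simulate_curve


@pytest.fixture
def config():
    return SledTestConfig()


@pytest.fixture
def noisefree_params():
    """Ramp to 80 mN then flat sliding at 40 mN: every feature is exact."""
    return SimParams(
        static_force_true=80.0,
        loading_stiffness=40.0,
        sliding_baseline=40.0,
        drift_slope=0.0,
        event_rate=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def noisefree_curve(noisefree_params, config):
    curve, truth = simulate_curve(noisefree_params, config, seed=0)
    return curve, truth


@pytest.fixture
def noisy_params():
    """Realistic mid-strength test: events well above sensor noise."""
    return SimParams(
        static_force_true=80.0,
        loading_stiffness=40.0,
        sliding_baseline=40.0,
        event_rate=1.5,
        amplitude_log_mean=2.3,
        amplitude_log_sd=0.4,
        noise_sd=1.0,
    )


def sawtooth_curve(n_teeth=24, window_mm=15.0, tooth_height=10.0, base=50.0,
                   ramp_peak=80.0, dx=0.06):
    """Constructed trace: linear ramp to ``ramp_peak`` at 2 mm, then
    ``n_teeth`` identical symmetric teeth spread over ``window_mm``."""
    d_peak = 2.0
    x = np.arange(0, d_peak + window_mm + dx, dx)
    y = np.where(x <= d_peak, ramp_peak / d_peak * x, 0.0)
    post = x > d_peak
    period = window_mm / n_teeth
    phase = (x[post] - d_peak) / period
    tri = 1.0 - np.abs(2.0 * (phase % 1.0) - 1.0)  # 0..1..0 triangle
    y[post] = base - tooth_height / 2 + tooth_height * tri
    return x, y
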