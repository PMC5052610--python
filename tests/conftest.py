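import numpy as np
import pytest

from aobr import CCurve, NormalizedCurve, ReactorConfig, TracerExperiment


@pytest.fixture
def default_config() -> ReactorConfig:
    """Six equal compartments, 17.88 L, 0.37 L/h, all feed upstream."""
    return ReactorConfig()


@pytest.fixture
def split_631_config() -> ReactorConfig:
    return ReactorConfig(feed_split=(0.6, 0, 0.3, 0, 0.1, 0))


def dense_experiment(duration_multiple: float = 10.0,
                     interval: float = 0.5) -> TracerExperiment:
    return TracerExperiment(duration_multiple=duration_multiple,
                            sampling_interval=interval)


@pytest.fixture
def cstr_curve() -> NormalizedCurve:
    """Densely sampled ideal single-CSTR response e^-theta on [0, 30]."""
    theta = np.linspace(0.0, 30.0, 6001)
    return NormalizedCurve(theta=theta, c_theta=np.exp(-theta))


def erlang_curve(n: int, upper: float = 30.0, npts: int = 6001) -> NormalizedCurve:
    """Analytic N-equal-tank impulse response in dimensionless form."""
    from math import factorial
    theta = np.linspace(0.0, upper, npts)
    c = n * (n * theta) ** (n - 1) * np.exp(-n * theta) / factorial(n - 1)
    return NormalizedCurve(theta=theta, c_theta=c)


def gaussian_pulse_curve(center: float, width: float = 0.02,
                         upper: float = 3.0, npts: int = 3001) -> NormalizedCurve:
    theta = np.linspace(0.0, upper, npts)
    c = np.exp(-0.5 * ((theta - center) / width) ** 2)
    return NormalizedCurve(theta=theta, c_theta=c)


@pytest.fixture
def simple_ccurve() -> CCurve:
    times = np.arange(0.0, 145.0, 6.0)
    conc = np.exp(-times / 48.0)
    return CCurve(times=times, concentrations=conc, c0=1.0, nominal_hrt=48.0)
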