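import numpy as np
import pytest

from shrubmass import (CalibSample, InternodeSample, LogLogAllometry,
                       SimConfig, fit_density_loglog, fit_loglog)


@pytest.fixture(scope="session")
def four_point_fit() -> LogLogAllometry:
    """Hand-checkable fit: ln D = {0,1,2,3}, ln M = {1.0, 3.4, 6.1, 8.5}.

    Closed-form OLS gives slope 2.52, intercept 0.97 and
    residual_scale = sqrt(0.018/2) ~ 0.094868.
    """
    return LogLogAllometry().fit(np.exp([0.0, 1.0, 2.0, 3.0]),
                                 np.exp([1.0, 3.4, 6.1, 8.5]))


@pytest.fixture(scope="session")
def noiseless_tip_fit() -> LogLogAllometry:
    """Exact allometry M = 2 * D**2.5 -> zero residual scale."""
    d = np.array([2.0, 4.0, 8.0])
    return fit_loglog([CalibSample(x, 2.0 * x**2.5) for x in d])


@pytest.fixture(scope="session")
def noiseless_internode_fit():
    """Exact proportional internode model mass = 0.8 * volume (kg/L)."""
    vols = np.array([0.5, 1.0, 2.0, 5.0])
    samples = []
    for v in vols:
        # cylinder of diameter 10 cm with length chosen to hit volume v litres
        length = v * 1000.0 / (np.pi * 100.0 / 4.0)
        samples.append(InternodeSample(10.0, 10.0, length, 0.8 * v))
    return fit_density_loglog(samples)


@pytest.fixture
def small_config() -> SimConfig:
    """Simulator config scaled down for quick structural tests."""
    return SimConfig(mean_shrubs_per_plot=5.0)
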