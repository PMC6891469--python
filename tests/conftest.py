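import numpy as np
import pytest

from fpmkit.experiments import factor_recovery_benchmark, resolution_benchmark
from fpmkit.system import LEDArrayGeometry, OpticalSystem


@pytest.fixture
def optics():
    return OpticalSystem()


@pytest.fixture
def geom():
    return LEDArrayGeometry()


@pytest.fixture(scope="session")
def resolution_run():
    """The synthetic resolution experiment: bar chart, LED rings 0-9,
    lognormal brightness factors, full camera noise, SA-embedded recon."""
    return resolution_benchmark(seed=1)


@pytest.fixture(scope="session")
def factor_recovery_run():
    """Same acquisition without camera noise, reconstructed with and
    without the simulated-annealing intensity correction."""
    return factor_recovery_benchmark(seed=1)
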