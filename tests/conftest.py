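import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DT = 0.5
F_STIM = 0.025  # Hz, shared stimulus oscillation frequency


@pytest.fixture
def time_grid():
    return np.arange(0.0, 600.0, DT)


@pytest.fixture
def sinusoid(time_grid):
    """Unit 0.025-Hz sinusoid on the standard 600-s grid."""
    from thermophase.preprocess import CalciumSignal

    return CalciumSignal(time_grid, np.sin(2 * np.pi * F_STIM * time_grid))


@pytest.fixture
def delayed_pair(time_grid):
    """Factory: (signal, copy delayed by `delay` seconds) on a common grid."""
    from thermophase.preprocess import CalciumSignal

    def make(delay: float, y=None):
        yy = np.sin(2 * np.pi * F_STIM * time_grid) if y is None else y
        k = int(round(delay / DT))
        if k == 0:
            s = CalciumSignal(time_grid, yy)
            return s, CalciumSignal(time_grid, yy.copy())
        return (
            CalciumSignal(time_grid[k:], yy[k:]),
            CalciumSignal(time_grid[k:], yy[:-k]),
        )

    return make
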