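import numpy as np
import pytest

from rancistab import ConductivityTrace


@pytest.fixture
def piecewise_trace() -> ConductivityTrace:
    """Flat baseline at 1.0 until t=10 h, then a linear rise of slope 5.

    The baseline/tangent intersection is exactly 10.0 h.
    """
    t = np.arange(0, 20.0001, 0.05)
    c = np.where(t <= 10, 1.0, 1.0 + 5 * (t - 10))
    return ConductivityTrace("pw", 110.0, 25.0, 1, t, c)


@pytest.fixture
def logistic_trace() -> ConductivityTrace:
    """Noise-free logistic c(t) = 1 + 50 / (1 + exp(-2 (t - 12))).

    Analytic tangent-method OSI: the maximal slope A*k/4 = 25 sits at the
    centre t=12 where c = 1 + A/2; intersecting that tangent with the flat
    baseline at 1 gives t = 12 - (A/2)/(A k/4) = 12 - 2/k = 11.0 h.
    """
    t = np.arange(0, 24.0001, 0.05)
    c = 1 + 50 / (1 + np.exp(-2 * (t - 12)))
    return ConductivityTrace("lg", 110.0, 25.0, 1, t, c)


@pytest.fixture
def flat_trace() -> ConductivityTrace:
    t = np.arange(0, 24.0001, 0.05)
    return ConductivityTrace("flat", 110.0, 25.0, 1, t, np.ones_like(t))


@pytest.fixture
def grid_means():
    """Published-style cell-mean OSI grid: airflow -> [(T, mean OSI h)]."""
    return {
        15.0: [(110.0, 13.2), (120.0, 5.2), (130.0, 2.4)],
        20.0: [(110.0, 14.9), (120.0, 5.2), (130.0, 2.5)],
        25.0: [(110.0, 13.5), (120.0, 5.4), (130.0, 2.9)],
    }
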