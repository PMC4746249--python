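import math

import pytest

from btexcsia import DeltaValue, IsotopeSeries, Measurement


def exact_rayleigh_series(
    f_values,
    eps_C=-2.4,
    eps_H=-57.0,
    delta0_C=-25.2,
    delta0_H=-43.5,
    c0=12.0,
):
    """Noiseless closed-system fractionation trajectory.

    Built directly from the distillation law delta_t = (delta_0 + 1000) *
    f**(eps/1000) - 1000, independent of the simulator, so it can serve as an
    oracle for both the simulator and the fitting code.
    """
    ms = []
    for i, f in enumerate(f_values):
        d13 = (delta0_C + 1000.0) * f ** (eps_C / 1000.0) - 1000.0
        d2 = (delta0_H + 1000.0) * f ** (eps_H / 1000.0) - 1000.0
        ms.append(
            Measurement(
                time=float(i),
                compound="benzene",
                conc=c0 * f,
                delta13C=DeltaValue("C", d13),
                delta2H=DeltaValue("H", d2),
            )
        )
    return IsotopeSeries("benzene", ms)


def ols_slope_bruteforce(x, y):
    """Closed-form normal-equation slope/intercept, written independently of
    the statsmodels-backed fitting path."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


@pytest.fixture
def paper_like_series():
    """Five-point exact trajectory over the study's residual-fraction span."""
    return exact_rayleigh_series([1.0, 0.8, 0.6, 0.4, 0.19])
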