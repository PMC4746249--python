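import math

import numpy as np
import pytest

from btexcsia import (
    BENZENE_POSITIONS,
    PositionParams,
    akie,
    epsilon_reactive_position,
    fit_rayleigh,
)
from btexcsia.isotope_core import DeltaValue, IsotopeDomainError, IsotopeSeries, Measurement
from btexcsia.rayleigh import rayleigh_points

from conftest import exact_rayleigh_series, ols_slope_bruteforce


class TestExactModelRecovery:
    def test_noiseless_series_recovered_to_machine_precision(self, paper_like_series):
        fit = fit_rayleigh(paper_like_series, "C")
        assert fit.epsilon_bulk == pytest.approx(-2.4, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        fit_h = fit_rayleigh(paper_like_series, "H")
        assert fit_h.epsilon_bulk == pytest.approx(-57.0, abs=1e-9)

    def test_random_draws_recovered(self):
        # the linearized form is exact, not an approximation: any eps, any
        # delta_0, any f grid must be recovered essentially exactly
        rng = np.random.default_rng(42)
        for _ in range(100):
            eps = -rng.uniform(0.1, 100.0)
            d0 = rng.uniform(-200.0, 200.0)
            n = rng.integers(3, 12)
            f = np.sort(rng.uniform(0.05, 1.0, size=n))[::-1]
            f[0] = 1.0
            series = exact_rayleigh_series(f, eps_C=eps, delta0_C=d0)
            fit = fit_rayleigh(series, "C")
            assert abs(fit.epsilon_bulk - eps) < 1e-9
            assert fit.r_squared > 1.0 - 1e-12

    def test_two_point_forced_origin(self):
        # closed-form two-point solve: delta at f=0.5 from the exact law
        d_half = 974.8 * 0.5 ** (-0.0024) - 1000.0
        series = IsotopeSeries(
            "benzene",
            [
                Measurement(0.0, "benzene", 12.0, delta13C=DeltaValue("C", -25.2)),
                Measurement(1.0, "benzene", 6.0, delta13C=DeltaValue("C", d_half)),
            ],
        )
        fit = fit_rayleigh(series, "C", forced_origin=True)
        assert fit.epsilon_bulk == pytest.approx(-2.4, abs=1e-9)
        assert fit.forced_origin and fit.intercept == 0.0

    def test_constant_deltas_give_zero_epsilon(self):
        ms = [
            Measurement(float(i), "benzene", c, delta13C=DeltaValue("C", -25.2))
            for i, c in enumerate([12.0, 8.0, 4.0])
        ]
        fit = fit_rayleigh(IsotopeSeries("benzene", ms), "C")
        assert fit.epsilon_bulk == pytest.approx(0.0, abs=1e-12)


class TestOracleEquivalence:
    def test_ols_matches_bruteforce_normal_equations(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 11)
            f = np.sort(rng.uniform(0.1, 1.0, size=n))[::-1]
            f[0] = 1.0
            series = exact_rayleigh_series(f, eps_C=-3.1)
            # perturb deltas so the fit is not degenerate-exact
            for i, m in enumerate(series.measurements):
                m.delta13C = DeltaValue("C", m.delta13C.value + 0.3 * rng.standard_normal())
            x, y = rayleigh_points(series, "C")
            slope, intercept = ols_slope_bruteforce(list(x), list(y))
            fit = fit_rayleigh(series, "C")
            assert fit.epsilon_bulk / 1000.0 == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)


class TestStatisticalRecovery:
    def test_ci_covers_true_epsilon_at_nominal_rate(self):
        # study design: delta_0 = -25.2, f from 1 to 0.19, sigma_C = 0.3
        # permil, 8-12 points; two-sided 95% t-interval should cover the true
        # eps_C in 90-99% of noisy realizations
        rng = np.random.default_rng(123)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            n = int(rng.integers(8, 13))
            f = np.linspace(1.0, 0.19, n)
            series = exact_rayleigh_series(f)
            for m in series.measurements:
                m.delta13C = DeltaValue("C", m.delta13C.value + 0.3 * rng.standard_normal())
            fit = fit_rayleigh(series, "C")
            if abs(fit.epsilon_bulk + 2.4) <= fit.ci95_half_width:
                covered += 1
        assert 0.90 * n_sim <= covered <= 0.99 * n_sim


class TestFitPreconditions:
    def test_too_few_points(self, paper_like_series):
        short = IsotopeSeries("benzene", paper_like_series.measurements[:2])
        with pytest.raises(ValueError, match="fit_rayleigh"):
            fit_rayleigh(short, "C")

    def test_zero_concentration_rejected(self, paper_like_series):
        series = exact_rayleigh_series([1.0, 0.5, 0.25])
        series.measurements[2].conc = 0.0
        with pytest.raises(IsotopeDomainError):
            fit_rayleigh(series, "C")

    def test_zero_variance_in_f_rejected(self):
        ms = [
            Measurement(float(i), "benzene", 12.0, delta13C=DeltaValue("C", -25.2 + i))
            for i in range(3)
        ]
        with pytest.raises(IsotopeDomainError):
            fit_rayleigh(IsotopeSeries("benzene", ms), "C")


class TestPositionCorrectionAndAkie:
    def test_benzene_identity(self):
        assert epsilon_reactive_position(-2.4, BENZENE_POSITIONS) == pytest.approx(-2.4)

    def test_toluene_like_scaling(self):
        pos = PositionParams(z=1, n_total=7, x_reactive=1)
        assert epsilon_reactive_position(-1.0, pos) == pytest.approx(-7.0)

    @pytest.mark.parametrize(
        "eps, expected",
        [(-2.4, 1.0146), (0.0, 1.0)],
    )
    def test_akie_values(self, eps, expected):
        assert round(akie(eps).akie, 4) == pytest.approx(expected)

    def test_akie_hydrogen_from_printed_epsilon(self):
        # formula arithmetic on eps_H = -57: 1/(1 - 0.342)
        assert akie(-57.0).akie == pytest.approx(1.0 / 0.658, rel=1e-12)

    def test_akie_monotone_decreasing_and_unity_at_zero(self):
        eps_grid = np.linspace(-100.0, 50.0, 40)
        values = [akie(e).akie for e in eps_grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert akie(0.0).akie == 1.0

    def test_akie_sign_relation(self):
        assert akie(-5.0).akie > 1.0
        assert akie(5.0).akie < 1.0

    def test_akie_domain_error(self):
        with pytest.raises(IsotopeDomainError):
            akie(-200.0)  # 1 + 6*(-0.2) < 0

    def test_akie_ci_transform_takes_larger_half_width(self):
        res = akie(-57.0, ci95_half_width=1.0)
        lo = 1.0 / (1.0 + 6 * (-58.0) / 1000.0)
        hi = 1.0 / (1.0 + 6 * (-56.0) / 1000.0)
        assert res.ci95_half_width == pytest.approx(
            max(abs(lo - res.akie), abs(hi - res.akie))
        )
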