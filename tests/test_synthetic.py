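import dataclasses
import math

import numpy as np
import pytest

from btexcsia import (
    CompoundKinetics,
    MicrocosmConfig,
    fit_lambda,
    fit_rayleigh,
    study_scenario,
    residual_percentage,
    simulate_microcosm,
)
from btexcsia.kinetics import detect_halt, detect_lag
from btexcsia.synthetic import config_from_yaml, config_to_yaml


def _noiseless(cfg):
    return dataclasses.replace(
        cfg, sigma_delta13C=0.0, sigma_delta2H=0.0, sigma_conc_rel=0.0
    )


@pytest.fixture(scope="module")
def isotope_cfg():
    return study_scenario("benzene_isotope")


class TestDeterminism:
    def test_identical_seed_identical_output(self, isotope_cfg):
        a_live, a_ctrl = simulate_microcosm(isotope_cfg)
        b_live, b_ctrl = simulate_microcosm(isotope_cfg)
        for sa, sb in zip(a_live.values(), b_live.values()):
            for ma, mb in zip(sa.measurements, sb.measurements):
                assert ma.conc == mb.conc
                assert ma.delta13C.value == mb.delta13C.value
                assert ma.delta2H.value == mb.delta2H.value

    def test_different_seed_differs(self, isotope_cfg):
        a, _ = simulate_microcosm(isotope_cfg)
        b, _ = simulate_microcosm(dataclasses.replace(isotope_cfg, seed=isotope_cfg.seed + 1))
        assert a["benzene"].measurements[1].conc != b["benzene"].measurements[1].conc


class TestExactModelRoundTrip:
    def test_noiseless_fit_recovers_epsilons_exactly(self, isotope_cfg):
        live, _ = simulate_microcosm(_noiseless(isotope_cfg))
        fit_c = fit_rayleigh(live["benzene"], "C")
        fit_h = fit_rayleigh(live["benzene"], "H")
        assert fit_c.epsilon_bulk == pytest.approx(-2.4, abs=1e-9)
        assert fit_h.epsilon_bulk == pytest.approx(-57.0, abs=1e-9)
        assert fit_c.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_lambda_within_three_percent_of_ratio(self, isotope_cfg):
        live, _ = simulate_microcosm(_noiseless(isotope_cfg))
        fit = fit_lambda(live["benzene"])
        assert fit.lambda_slope == pytest.approx(23.75, rel=0.03)

    def test_zero_rates_give_constant_series(self):
        cfg = MicrocosmConfig(
            compounds=(CompoundKinetics("benzene", 10.0, rate_per_day=0.0),),
            sampling_times=(0.0, 10.0, 20.0),
            internal_standard=None,
            seed=5,
        )
        live, ctrl = simulate_microcosm(_noiseless(cfg))
        for ml, mc in zip(live["benzene"].measurements, ctrl["benzene"].measurements):
            assert ml.conc == mc.conc == 10.0
            assert ml.delta13C.value == pytest.approx(-25.2)
            assert ml.delta2H.value == pytest.approx(-43.5)


class TestMassBalance:
    def test_residual_recovers_f_bio_exactly_with_internal_standard(self):
        cfg = _noiseless(study_scenario("btex"))
        live, ctrl = simulate_microcosm(cfg)
        curve = residual_percentage(
            live["ethylbenzene"], ctrl["ethylbenzene"], "o-xylene"
        )
        eb = next(c for c in cfg.compounds if c.compound == "ethylbenzene")
        for t, r in zip(curve.times, curve.residual_pct):
            f_bio = math.exp(-eb.rate_per_day * max(0.0, t - eb.lag_days))
            assert r == pytest.approx(100.0 * f_bio, rel=1e-9)

    def test_halt_never_fires_during_clean_removal(self):
        cfg = _noiseless(study_scenario("btex"))
        live, ctrl = simulate_microcosm(cfg)
        curve = residual_percentage(live["toluene"], ctrl["toluene"], "o-xylene")
        assert detect_halt(curve)[0] is False


class TestPaperScenario:
    def test_epsilon_pair_and_start_levels(self):
        cfg = study_scenario("btex")
        assert (cfg.eps_C, cfg.eps_H) == (-2.4, -57.0)
        assert all(c.c0 == 100.0 for c in cfg.compounds)
        iso = study_scenario("benzene_isotope")
        assert iso.compounds[0].c0 == 12.0

    def test_xylenes_not_degradable_and_oxylene_is_internal_standard(self):
        cfg = study_scenario("btex")
        by_name = {c.compound: c for c in cfg.compounds}
        for xyl in ("o-xylene", "m-xylene", "p-xylene"):
            assert not by_name[xyl].degradable
        assert cfg.internal_standard == "o-xylene"

    def test_sequential_onset_order(self):
        # ethylbenzene starts before toluene before benzene
        live, ctrl = simulate_microcosm(study_scenario("btex"))
        lags = {}
        for compound in ("ethylbenzene", "toluene", "benzene"):
            curve = residual_percentage(live[compound], ctrl[compound], "o-xylene")
            # generous threshold so 2% concentration noise cannot fake an onset
            lags[compound] = detect_lag(curve, threshold_pct=10, sustain_points=3)
        assert lags["ethylbenzene"] < lags["toluene"] < lags["benzene"]

    def test_inhibition_freezes_removal(self):
        cfg = _noiseless(study_scenario("btex"))
        cfg = dataclasses.replace(cfg, inhibition_time=139.0)
        live, ctrl = simulate_microcosm(cfg)
        curve = residual_percentage(live["benzene"], ctrl["benzene"], "o-xylene")
        after = [r for t, r in zip(curve.times, curve.residual_pct) if t >= 139.0]
        assert max(after) - min(after) < 1e-9  # frozen once inhibitor added


class TestNoiseCalibration:
    def test_delta_noise_sd_matches_configured_sigma(self):
        # repeated draws of the same design: sample SD of delta13C at fixed f
        # converges to the configured 0.3 permil
        cfg = study_scenario("benzene_isotope")
        draws = []
        for seed in range(1000):
            live, _ = simulate_microcosm(dataclasses.replace(cfg, seed=seed))
            draws.append(live["benzene"].measurements[5].delta13C.value)
        sd = float(np.std(draws, ddof=1))
        assert sd == pytest.approx(cfg.sigma_delta13C, rel=0.1)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, isotope_cfg):
        p = tmp_path / "cfg.yaml"
        config_to_yaml(isotope_cfg, p)
        assert config_from_yaml(p) == isotope_cfg

    def test_seed_required_in_file(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "compounds:\n- {compound: benzene, c0: 12.0}\nsampling_times: [0, 1]\n",
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match="seed"):
            config_from_yaml(p)

    def test_invalid_config_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            MicrocosmConfig(
                compounds=(CompoundKinetics("benzene", 12.0),),
                sampling_times=(5.0, 1.0),
                internal_standard=None,
                seed=1,
            )
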