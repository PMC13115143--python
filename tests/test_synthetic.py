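"""Synthetic storage-study generator: determinism, zero-noise exactness,
label coupling, photobleaching, and end-to-end parameter recovery."""

import math

import numpy as np
import pytest

from freshlabel import (
    SimulationConfig,
    calibrate_delta_e,
    delta_e,
    fit_arrhenius,
    fit_first_order,
    make_validation_design,
    remaining_shelf_life,
    simulate_label_readings,
    simulate_photodegradation,
    simulate_tvbn_study,
    tvbn_from_delta_e,
)
from freshlabel.shelflife import Calibration, ShelfLifeModel
from freshlabel.synthetic import DEFAULT_SCHEDULES, design_rows


def fits_by_temperature(observations):
    temps = sorted({o.temperature_C for o in observations})
    return [
        fit_first_order([o for o in observations if o.temperature_C == T])
        for T in temps
    ]


class TestSimulateTvbnStudy:
    def test_zero_noise_matches_closed_form(self, noiseless_config):
        obs = simulate_tvbn_study(noiseless_config)
        for o in obs:
            k = noiseless_config.true_rate(o.temperature_C)
            expected = noiseless_config.true_a0 * math.exp(k * o.time_h)
            assert o.tvbn == pytest.approx(expected, rel=1e-12)

    def test_zero_noise_fit_recovers_rates_exactly(self, noiseless_config):
        for fit in fits_by_temperature(simulate_tvbn_study(noiseless_config)):
            assert fit.k == pytest.approx(
                noiseless_config.true_rate(fit.temperature_C), rel=1e-10
            )
            assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_spoilage_crossing_at_28C(self, noiseless_config):
        """With the study constants, shrimp at 28 °C spoil between 24 and 36 h."""
        k = noiseless_config.true_rate(28.0)
        crossing = math.log(30.0 / noiseless_config.true_a0) / k
        assert 24.0 < crossing < 36.0

    def test_design_shape_and_positivity(self):
        cfg = SimulationConfig(seed=3)
        obs = simulate_tvbn_study(cfg)
        expected_n = cfg.replicates * sum(
            len(DEFAULT_SCHEDULES[T]) for T in cfg.temperatures_C
        )
        assert len(obs) == expected_n
        assert all(o.tvbn > 0 for o in obs)
        for o in obs:
            assert o.time_h in DEFAULT_SCHEDULES[o.temperature_C]

    def test_seed_determinism(self):
        a = simulate_tvbn_study(SimulationConfig(seed=12))
        b = simulate_tvbn_study(SimulationConfig(seed=12))
        c = simulate_tvbn_study(SimulationConfig(seed=13))
        assert a == b
        assert a != c

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sigma_ln=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(color_direction=(1.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            SimulationConfig(schedules={0.0: (6.0, 12.0)}, temperatures_C=(0.0,))


class TestSimulateLabelReadings:
    def test_intercept_tvbn_gives_baseline(self, noiseless_config):
        from freshlabel import TvbnObservation

        tv = [TvbnObservation(time_h=0.0, temperature_C=25.0, tvbn=0.6)]
        (reading,) = simulate_label_readings(tv, noiseless_config)
        assert delta_e(noiseless_config.baseline_lab, reading.color) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_inverse_calibration_coupling(self, noiseless_config):
        from freshlabel import TvbnObservation

        tv = [TvbnObservation(time_h=8.0, temperature_C=25.0, tvbn=10.324)]
        (reading,) = simulate_label_readings(tv, noiseless_config)
        assert delta_e(noiseless_config.baseline_lab, reading.color) == pytest.approx(
            6.8, rel=1e-9
        )

    def test_zero_noise_calibration_round_trip(self, noiseless_config):
        """Fitting ΔE (vs the fresh baseline) against TVB-N on simulated
        readings recovers the true calibration line."""
        obs = simulate_tvbn_study(noiseless_config)
        colors = simulate_label_readings(obs, noiseless_config)
        pairs = [
            (delta_e(noiseless_config.baseline_lab, c.color), o.tvbn)
            for c, o in zip(colors, obs)
            if o.tvbn > noiseless_config.calib_intercept
        ]
        calib = calibrate_delta_e(pairs)
        assert calib.slope == pytest.approx(1.43, rel=1e-8)
        assert calib.intercept == pytest.approx(0.6, rel=1e-6)
        assert calib.r_squared == pytest.approx(1.0, abs=1e-10)


class TestSimulatePhotodegradation:
    def test_zero_rate_no_degradation(self):
        series = simulate_photodegradation(0.0)
        assert [c for _, c in series] == pytest.approx([100.0] * 4)

    @pytest.mark.parametrize(
        "kp, expected_24h", [(0.1723, 98.4), (0.0412, 62.8)]
    )
    def test_derived_rates_reproduce_study_percentages(self, kp, expected_24h):
        series = simulate_photodegradation(kp, c0=100.0)
        t, c24 = series[-1]
        assert t == 24.0
        assert 100.0 * (1 - c24 / 100.0) == pytest.approx(expected_24h, abs=0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_photodegradation(-0.1)


class TestMakeValidationDesign:
    def truth_model(self, config):
        return ShelfLifeModel.from_arrhenius(config.true_arrhenius())

    def test_zero_noise_self_consistency(self, noiseless_config):
        """Predictions from the true model on noiseless designs are exact."""
        calib = Calibration(
            slope=noiseless_config.calib_slope,
            intercept=noiseless_config.calib_intercept,
        )
        model = self.truth_model(noiseless_config)
        for temp, _, de, observed in design_rows(
            make_validation_design(noiseless_config)
        ):
            pred = remaining_shelf_life(
                tvbn_from_delta_e(de, calib), temp, model
            ).remaining_h
            assert pred == pytest.approx(observed, rel=1e-9)

    def test_deterministic_and_spoilage_flagging(self):
        cfg = SimulationConfig(seed=21)
        a = make_validation_design(cfg)
        assert a == make_validation_design(cfg)
        late = make_validation_design(cfg, validation_times={20.0: (2000.0,)})
        assert late[0].spoiled and late[0].observed_h < 0
        assert design_rows(late) == []

    def test_noisy_designs_stay_accurate(self):
        """Median worst-case RE over seeds stays below 15% with 5% noise."""
        calib = Calibration(slope=1.43, intercept=0.6)
        max_res = []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed)
            model = self.truth_model(cfg)
            res = [
                abs(
                    remaining_shelf_life(
                        tvbn_from_delta_e(de, calib), t, model
                    ).remaining_h
                    - obs
                )
                / obs
                * 100.0
                for t, _, de, obs in design_rows(make_validation_design(cfg))
            ]
            max_res.append(max(res))
        assert np.median(max_res) < 15.0


class TestEndToEndRecovery:
    def test_zero_noise_recovers_all_parameters(self, noiseless_config):
        obs = simulate_tvbn_study(noiseless_config)
        arr = fit_arrhenius(fits_by_temperature(obs))
        assert arr.ea == pytest.approx(noiseless_config.true_ea, rel=1e-8)
        assert arr.k0 == pytest.approx(noiseless_config.true_k0, rel=1e-8)
        colors = simulate_label_readings(obs, noiseless_config)
        calib = calibrate_delta_e(
            [
                (delta_e(noiseless_config.baseline_lab, c.color), o.tvbn)
                for c, o in zip(colors, obs)
                if o.tvbn > 0.6
            ]
        )
        assert calib.slope == pytest.approx(1.43, rel=1e-8)
        assert calib.intercept == pytest.approx(0.6, rel=1e-8)

    def test_noisy_recovery_is_unbiased_enough(self):
        errs = []
        for seed in range(20):
            obs = simulate_tvbn_study(SimulationConfig(seed=seed))
            arr = fit_arrhenius(fits_by_temperature(obs))
            errs.append(abs(arr.ea - 58958.0) / 58958.0)
        assert np.median(errs) < 0.05
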