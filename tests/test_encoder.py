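"""BSRM encoder: link functions, refractoriness, label grammar, calibration."""

from dataclasses import replace

import numpy as np
import pytest

from burstplex import (DRIVER, CalibrationError, EncoderParams,
                       MarkedSpikeTrain, SignalParams, SignalTrace, SpikeLabel,
                       calibrate_event_threshold, instantaneous_intensities,
                       refractory_kernel, sample_ou, simulate_bsrm,
                       simulate_population, simulate_reference)


def _const_trace(value, n=100, dt=0.1):
    return SignalTrace(0.0, dt, np.full(n, float(value)))


class TestIntensities:
    def test_event_rate_equals_lambda0_at_threshold(self):
        p = EncoderParams(tau_rel=6.0, theta_e=1.5, lambda0=10.0)
        rate, _ = instantaneous_intensities(_const_trace(1.5), _const_trace(0.0), p)
        np.testing.assert_allclose(rate.values, 10.0)

    def test_burst_probability_is_half_at_threshold(self):
        p = EncoderParams(tau_rel=6.0)  # theta_b = 4.5
        _, prob = instantaneous_intensities(_const_trace(0.0), _const_trace(4.5), p)
        np.testing.assert_allclose(prob.values, 0.5)

    def test_refractory_kernel_closed_form(self):
        # elapsed exactly tau_rel -> -1/e; negative elapsed -> 0
        assert refractory_kernel(6.0, 6.0) == pytest.approx(-np.exp(-1.0))
        assert refractory_kernel(-1.0, 6.0) == 0.0

    def test_mismatched_grids_rejected(self):
        p = EncoderParams(tau_rel=6.0)
        with pytest.raises(ValueError):
            instantaneous_intensities(_const_trace(0, n=50), _const_trace(0, n=60), p)


class TestSimulation:
    def test_zero_burst_probability_gives_only_singlets(self, short_inputs):
        drv, _ = short_inputs
        quiet = SignalTrace(0.0, drv.dt, np.zeros(len(drv)))
        p = EncoderParams(tau_rel=6.0, theta_e=0.1, theta_b=1e15)
        tr = simulate_bsrm(p, drv, quiet, 1)
        assert len(tr) > 50
        assert np.all(tr.labels == SpikeLabel.SINGLET_EVENT)

    def test_refractoriness_and_grammar(self, small_raster):
        for tr in small_raster:
            assert tr.isis().min() >= 2.0
            tr.check_grammar(n_ib=1)

    def test_operating_point_statistics(self, small_raster):
        # calibrated-ish threshold: ~10 Hz events, burst fraction near 0.2
        assert small_raster.event_rate_hz() == pytest.approx(10.0, abs=1.5)
        assert small_raster.burst_fraction() == pytest.approx(0.22, abs=0.06)

    def test_intra_burst_isi_matches_truncated_gamma(self, short_inputs):
        drv, mod = short_inputs
        p = EncoderParams(tau_rel=6.0, theta_e=0.1)
        rng = np.random.default_rng(0)
        ib_isis = []
        for seed in range(30):
            tr = simulate_bsrm(p, drv, mod, seed)
            prev_t = np.r_[np.nan, tr.times[:-1]]
            mask = tr.labels == SpikeLabel.INTRA_BURST
            ib_isis.append((tr.times - prev_t)[mask])
        ib_isis = np.concatenate(ib_isis)
        # independent oracle: rejection-sample the same truncated gamma
        ref = rng.gamma(1.5, 20.0 / 3.0, 200_000)
        ref = ref[ref >= 2.0][: ib_isis.size * 10]
        assert ib_isis.min() >= 2.0
        assert ib_isis.mean() == pytest.approx(ref.mean(), rel=0.05)
        # typical intra-burst rate in the 100-200 Hz band (the right-skewed
        # gamma tail pulls the mean rate slightly below it)
        assert 100.0 <= 1000.0 / np.median(ib_isis) <= 200.0

    def test_seed_determinism(self, short_inputs):
        drv, mod = short_inputs
        p = EncoderParams(tau_rel=6.0, theta_e=0.1)
        a = simulate_bsrm(p, drv, mod, 5)
        b = simulate_bsrm(p, drv, mod, 5)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_dt_invariance_of_event_rate(self):
        # halving the simulation step leaves the long-run event rate
        # unchanged within Monte-Carlo error
        p = EncoderParams(tau_rel=6.0, theta_e=-0.10)
        rates = []
        for dt in (0.2, 0.1):
            ss = np.random.SeedSequence(77)
            d, m, s = ss.spawn(3)
            drv = sample_ou(DRIVER, dt, 200_000.0, d)
            mod = sample_ou(SignalParams(20.0, 36.0), dt, 200_000.0, m)
            rates.append(simulate_bsrm(p, drv, mod, s).event_rate_hz())
        assert rates[0] == pytest.approx(rates[1], abs=0.7)


class TestPopulation:
    def test_singleton_population_matches_single_cell(self, short_inputs):
        drv, mod = short_inputs
        p = EncoderParams(tau_rel=6.0, theta_e=0.1, n_pop=1)
        ss = np.random.SeedSequence(31)
        pop = simulate_population(p, drv, mod, ss)
        solo = simulate_bsrm(p, drv, mod, np.random.SeedSequence(31).spawn(1)[0])
        np.testing.assert_array_equal(pop.trains[0].times, solo.times)

    def test_psth_tracks_driver_rate(self, small_raster, short_inputs):
        drv, mod = short_inputs
        psth = np.zeros(int(small_raster.duration))
        for tr in small_raster:
            ev = tr.event_times
            np.add.at(psth, np.minimum(ev.astype(int), psth.size - 1), 1.0)
        rate, _ = instantaneous_intensities(drv.decimate(10), mod.decimate(10),
                                            small_raster.params)
        # clearly positive; the refractory suppression missing from the
        # open-loop intensity trace keeps it well below 1
        r = np.corrcoef(psth, rate.values[: psth.size])[0, 1]
        assert r > 0.1

    def test_different_master_seeds_same_statistics(self, short_inputs):
        drv, mod = short_inputs
        p = EncoderParams(tau_rel=6.0, theta_e=-0.10, n_pop=10)
        a = simulate_population(p, drv, mod, 101)
        b = simulate_population(p, drv, mod, 202)
        assert a.trains[0].times.size != b.trains[0].times.size or not np.array_equal(
            a.trains[0].times, b.trains[0].times)
        assert a.event_rate_hz() == pytest.approx(b.event_rate_hz(), rel=0.15)


class TestCalibration:
    def test_closed_form_recovered_in_degenerate_limit(self):
        # constant potential: rate = lambda0 exp((v0 - theta)/alpha)
        # -> theta = v0 - alpha ln(target/lambda0)
        p = EncoderParams(tau_rel=1e-6, theta_e=0.0, delta_ref=0.0,
                          theta_b=1e15, lambda0=10.0)
        target = 5.0
        expected = -2.0 * np.log(target / 10.0)
        theta = calibrate_event_threshold(
            p, target, SignalParams(10.0, 0.0), SignalParams(20.0, 0.0),
            tolerance=0.3, seed=3, sim_duration=300_000.0)
        assert theta == pytest.approx(expected, abs=0.15)

    def test_threshold_nonincreasing_in_tau_rel(self):
        thetas = [calibrate_event_threshold(EncoderParams(tau_rel=tr), 10.0,
                                            tolerance=0.5, seed=13,
                                            sim_duration=300_000.0)
                  for tr in (2.0, 7.0, 28.0)]
        assert thetas[0] >= thetas[1] - 0.02
        assert thetas[1] >= thetas[2] - 0.02

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_event_threshold(EncoderParams(tau_rel=6.0), 1e6,
                                      seed=1, sim_duration=50_000.0)


class TestReferences:
    def test_poisson_isi_mean_and_cv(self):
        tr = simulate_reference("poisson", rate=20.0, duration=2_000_000.0, seed=8)
        isis = tr.isis()
        assert isis.mean() == pytest.approx(50.0, rel=0.03)
        assert isis.std() / isis.mean() == pytest.approx(1.0, abs=0.03)

    def test_gamma_renewal_cv_matches_shape(self):
        tr = simulate_reference("gamma_renewal", rate=20.0, shape=0.5,
                                duration=2_000_000.0, seed=9)
        isis = tr.isis()
        assert isis.std() / isis.mean() == pytest.approx(np.sqrt(2.0), abs=0.05)
        assert isis.mean() == pytest.approx(50.0, rel=0.03)

    def test_refractory_shift_preserves_requested_rate(self):
        tr = simulate_reference("gamma_renewal", rate=10.0, shape=0.5,
                                delta_ref=2.0, duration=2_000_000.0, seed=10)
        assert tr.isis().min() >= 2.0
        assert tr.spike_rate_hz() == pytest.approx(10.0, rel=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference("weibull", rate=1.0, duration=1000.0)


class TestMarkedTrainContainer:
    def test_grammar_violation_detected(self):
        bad = MarkedSpikeTrain(np.array([1.0, 5.0]),
                               np.array([0, 2], dtype=np.int8), 10.0)
        with pytest.raises(ValueError):
            bad.check_grammar(1)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            MarkedSpikeTrain(np.array([2.0, 1.0]),
                             np.array([0, 0], dtype=np.int8), 10.0)

    def test_csv_round_trip(self, tmp_path, small_raster):
        tr = small_raster.trains[0]
        path = tmp_path / "train.csv"
        tr.to_csv(path)
        back = MarkedSpikeTrain.from_csv(path)
        np.testing.assert_allclose(back.times, tr.times, rtol=1e-9)
        np.testing.assert_array_equal(back.labels, tr.labels)
        assert back.duration == tr.duration
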