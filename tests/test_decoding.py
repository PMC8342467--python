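"""STP decoding: weight rules, population traces, synaptic filter, tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from burstplex import (EncoderParams, MarkedSpikeTrain, PopulationRaster,
                       STPParams, SignalTrace, SpikeLabel, SynapseParams,
                       decode_burst_fraction, perfect_weights,
                       population_activity, spike_weights, synaptic_kernel,
                       synaptic_potential, tune_decoder)


def _train(times, labels=None, duration=None):
    times = np.asarray(times, dtype=float)
    if labels is None:
        labels = np.zeros(times.size, dtype=np.int8)
    if duration is None:
        duration = (times[-1] + 10.0) if times.size else 10.0
    return MarkedSpikeTrain(times, np.asarray(labels, dtype=np.int8), duration)


class TestSTP1:
    def test_hand_example_depressing_and_facilitating(self):
        tr = _train([0.0, 30.0, 34.0])
        dep = spike_weights(tr, STPParams.stp1_depressing(10.0))
        fac = spike_weights(tr, STPParams.stp1_facilitating(10.0))
        np.testing.assert_array_equal(dep, [1.0, 1.0, 0.0])
        np.testing.assert_array_equal(fac, [0.0, 0.0, 1.0])

    def test_empty_train_gives_empty_weights(self):
        tr = _train([])
        assert spike_weights(tr, STPParams.stp1_depressing(10.0)).size == 0

    def test_rules_partition_every_spike(self):
        rng = np.random.default_rng(0)
        tr = _train(np.cumsum(rng.exponential(20.0, 200)))
        dep = spike_weights(tr, STPParams.stp1_depressing(15.0))
        fac = spike_weights(tr, STPParams.stp1_facilitating(15.0))
        np.testing.assert_array_equal(dep + fac, np.ones(200))


class TestSTP2:
    def test_single_pair_at_threshold_gives_half(self):
        # one preceding spike exactly theta_w earlier: kernel 0.5,
        # weight sigmoid(40*0.5 - 20) = 0.5
        tr = _train([0.0, 10.0])
        w = spike_weights(tr, STPParams.stp2_facilitating(10.0, 2.0))
        assert w[1] == pytest.approx(0.5, abs=1e-9)
        assert w[0] == pytest.approx(0.0, abs=1e-6)  # no predecessor

    def test_limit_to_stp1_for_isis_away_from_threshold(self):
        rng = np.random.default_rng(1)
        isis = np.concatenate([rng.uniform(2, 7, 50), rng.uniform(14, 60, 50)])
        rng.shuffle(isis)
        tr = _train(np.cumsum(isis))
        sharp_fac = spike_weights(tr, STPParams.stp1_facilitating(10.0))
        smooth_fac = spike_weights(tr, STPParams.stp2_facilitating(10.0, 0.05))
        np.testing.assert_allclose(smooth_fac, sharp_fac, atol=1e-5)

    @given(st.lists(st.floats(min_value=2.0, max_value=200.0),
                    min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_weights_bounded_for_every_rule(self, isis):
        tr = _train(np.cumsum(isis))
        for stp in (STPParams.stp1_depressing(12.0),
                    STPParams.stp1_facilitating(12.0),
                    STPParams.stp2_depressing(12.0, 3.0),
                    STPParams.stp2_facilitating(12.0, 3.0)):
            w = spike_weights(tr, stp)
            assert np.all(w >= 0.0) and np.all(w <= 1.0)


class TestPerfectWeights:
    def test_burst_free_train(self):
        tr = _train([1.0, 5.0, 9.0])
        np.testing.assert_array_equal(perfect_weights(tr, "event"), [1, 1, 1])
        np.testing.assert_array_equal(perfect_weights(tr, "burst"), [0, 0, 0])

    def test_doublet_marks_second_spike(self):
        tr = _train([1.0, 5.0, 11.0], labels=[1, 2, 0])
        np.testing.assert_array_equal(perfect_weights(tr, "event"), [1, 0, 1])
        np.testing.assert_array_equal(perfect_weights(tr, "burst"), [0, 1, 0])

    def test_event_weight_count_equals_event_count(self, small_raster):
        for tr in small_raster.trains[:5]:
            assert perfect_weights(tr, "event").sum() == tr.n_events


class TestPopulationActivity:
    def test_unit_weights_integrate_to_spike_count(self):
        tr = _train([1.0, 5.0, 9.0], duration=20.0)
        raster = PopulationRaster([tr], 20.0)
        a = population_activity(raster, STPParams.stp1_depressing(0.5), 1.0)
        assert a.values.sum() == pytest.approx(3.0)

    def test_identical_trains_average_to_one_train(self):
        tr = _train([1.0, 5.0, 9.0], duration=20.0)
        one = population_activity(PopulationRaster([tr], 20.0),
                                  STPParams.stp1_depressing(0.5), 1.0)
        many = population_activity(PopulationRaster([tr] * 5, 20.0),
                                   STPParams.stp1_depressing(0.5), 1.0)
        np.testing.assert_allclose(many.values, one.values)

    def test_sharp_rules_sum_to_unweighted_rate(self, small_raster):
        dep = population_activity(small_raster, STPParams.stp1_depressing(12.0))
        fac = population_activity(small_raster, STPParams.stp1_facilitating(12.0))
        total = sum(len(tr) for tr in small_raster)
        assert (dep.values + fac.values).sum() * len(small_raster) == pytest.approx(total)


class TestSynapticPotential:
    def test_zero_activity_rests_at_v_syn(self):
        a = SignalTrace(0.0, 1.0, np.zeros(100))
        u = synaptic_potential(a, SynapseParams(), n_pop=7)
        np.testing.assert_allclose(u.values, 1.0)

    def test_single_spike_impulse_response(self):
        # (1/N) and N cancel: u(t) = kappa_syn(t) + v_syn
        n = 50
        a = SignalTrace(0.0, 1.0, np.r_[1.0 / 8, np.zeros(n - 1)])
        u = synaptic_potential(a, SynapseParams(), n_pop=8)
        t = np.arange(n, dtype=float)
        np.testing.assert_allclose(u.values, synaptic_kernel(t, SynapseParams()) + 1.0,
                                   rtol=1e-9)

    def test_kernel_peak_time_closed_form(self):
        syn = SynapseParams(tau_rise=3.0, tau_decay=5.0)
        res = minimize_scalar(lambda t: -synaptic_kernel(t, syn),
                              bounds=(0.1, 30.0), method="bounded",
                              options={"xatol": 1e-12})
        assert res.x == pytest.approx(3.0 * np.log(8.0 / 3.0), abs=1e-6)

    def test_linearity_in_activity(self):
        rng = np.random.default_rng(2)
        a1 = SignalTrace(0.0, 1.0, rng.random(200))
        a2 = SignalTrace(0.0, 1.0, rng.random(200))
        syn = SynapseParams()
        u1 = synaptic_potential(a1, syn, 3).values - syn.v_syn
        u2 = synaptic_potential(a2, syn, 3).values - syn.v_syn
        both = SignalTrace(0.0, 1.0, a1.values + a2.values)
        u12 = synaptic_potential(both, syn, 3).values - syn.v_syn
        np.testing.assert_allclose(u12, u1 + u2, atol=1e-10)


class TestBurstFraction:
    def test_equal_traces_zero_lag_give_unity(self):
        u = SignalTrace(0.0, 1.0, np.full(50, 2.5))
        bf = decode_burst_fraction(u, u, 0.0)
        np.testing.assert_allclose(bf.values, 1.0)

    def test_resting_baselines_give_unity(self):
        u = SignalTrace(0.0, 1.0, np.full(50, 1.0))  # v_syn baseline
        bf = decode_burst_fraction(u, u, 9.0)
        np.testing.assert_allclose(bf.values, 1.0)

    def test_lag_shifts_denominator(self):
        ub = SignalTrace(0.0, 1.0, np.arange(1.0, 11.0))
        ue = SignalTrace(0.0, 1.0, np.arange(1.0, 11.0))
        bf = decode_burst_fraction(ub, ue, 2.0)
        np.testing.assert_allclose(bf.values, ub.values[2:] / ue.values[:-2])
        assert bf.t0 == pytest.approx(2.0)

    def test_invalid_lag_rejected(self):
        u = SignalTrace(0.0, 1.0, np.ones(10))
        with pytest.raises(ValueError):
            decode_burst_fraction(u, u, -1.0)
        with pytest.raises(ValueError):
            decode_burst_fraction(u, u, 0.5)


class TestTuning:
    def test_singleton_grid_returned(self, small_raster, short_inputs):
        drv, mod = short_inputs
        from burstplex import SpectralParams
        tw, lag, best, table = tune_decoder(
            small_raster, drv.decimate(10), mod.decimate(10), [14.0],
            lag_grid=(9.0,), spectral=SpectralParams(window_length=4.096))
        assert tw == 14.0 and lag == 9.0
        assert table[(14.0, 9.0)] == best

    def test_argmax_property_over_grid(self, small_raster, short_inputs):
        drv, mod = short_inputs
        from burstplex import SpectralParams
        grid = [6.0, 14.0, 30.0]
        tw, lag, best, table = tune_decoder(
            small_raster, drv.decimate(10), mod.decimate(10), grid,
            lag_grid=(9.0,), spectral=SpectralParams(window_length=4.096))
        assert best == max(table.values())
        assert table[(tw, lag)] == best

    def test_empty_grid_rejected(self, small_raster, short_inputs):
        drv, mod = short_inputs
        with pytest.raises(ValueError):
            tune_decoder(small_raster, drv.decimate(10), mod.decimate(10), [])
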