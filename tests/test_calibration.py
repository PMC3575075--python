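"""Calibration routines: fixed points, convergence, dispersion reduction.

Populations are kept small and measurement windows short; the full-size
calibration check lives in the acceptance suite.
"""

import numpy as np
import pytest

from spikesim.calibration import (calibrate_drivers, calibrate_excitability,
                                  calibrate_antennal_lobe, calibrate_tau_m,
                                  measure_tau_m)
from spikesim.core import Network, NeuronParams
from spikesim.substrate import NoiseModel, apply_fixed_pattern_noise


def _noisy_population(n=32, chip_seed=3, cv=0.3, median=1.0):
    net = Network("pop")
    net.add_population("p", n, NeuronParams())
    apply_fixed_pattern_noise(net, NoiseModel(fp_gl_cv=cv, fp_gl_median=median,
                                              fp_gmax_cv=0.0, fp_vth_sd=0.0,
                                              membrane_noise_sd=0.0,
                                              chip_seed=chip_seed))
    return net


class TestTauM:
    def test_noise_free_population_is_a_fixed_point(self):
        net = Network("clean")
        net.add_population("p", 4, NeuronParams())  # tau_m = 10 ms exactly
        res = calibrate_tau_m(net, 10.0, tol=0.05, window_ms=2000.0)
        assert res.iterations == 1
        assert all(res.converged.values())
        assert all(abs(s - 1.0) < 1e-9 for s in res.scale.values())

    def test_free_run_rate_example(self):
        """tau_m 10 ms, refrac 1 ms, exact 1/e threshold -> 1000/11 Hz."""
        net = Network("one")
        net.add_population("p", 1, NeuronParams())
        tau = measure_tau_m(net, tau_refrac=1.0, window_ms=10_000.0)
        rate = 1000.0 / (tau[0] + 1.0)
        assert rate == pytest.approx(1000.0 / 11.0, rel=0.01)

    def test_calibration_shrinks_dispersion(self):
        net = _noisy_population(n=32, cv=0.3)
        before = measure_tau_m(net, window_ms=4000.0)
        res = calibrate_tau_m(net, 10.0, tol=0.02, window_ms=4000.0)
        after = measure_tau_m(net, window_ms=4000.0)
        w_before = np.percentile(before, 80) - np.percentile(before, 20)
        w_after = np.percentile(after, 80) - np.percentile(after, 20)
        assert all(res.converged.values())
        assert w_after < w_before / 4
        assert abs(np.median(after) - 10.0) < 0.5

    def test_unmeasurable_neuron_is_flagged_not_kept(self):
        net = Network("stuck")
        net.add_population("p", 2, NeuronParams())
        # second neuron has an absurdly slow membrane: silent in the window
        net.set_neuron_param(1, g_l=1e-7)
        res = calibrate_tau_m(net, 10.0, tol=0.05, window_ms=500.0, max_iter=2)
        assert res.converged[0]
        assert 1 in res.flagged


class TestDrivers:
    def test_mismatched_drivers_equalized(self):
        net = Network("drv")
        net.add_population("p", 12, NeuronParams())
        net.add_sources("s", 2)
        drv = net.add_source_drivers("s", +1, 0.01, 5.0)
        net.driver_g_max[int(drv[1])] *= 2.0  # factor-2 mismatch
        res = calibrate_drivers(net, drv, [], target_rate=10.0,
                                probe_rate=300.0, window_ms=1000.0, seed=0)
        g = [net.driver_g_max[int(d)] for d in drv]
        assert all(res.converged.values())
        assert abs(g[0] - g[1]) / g[0] < 0.25  # equal strength after cal

    def test_inhibitory_integral_ratio(self):
        net = Network("drv2")
        net.add_population("p", 12, NeuronParams())
        net.add_sources("s", 2)
        d_e = net.add_source_drivers("s", +1, 0.01, 5.0)[:1]
        net.add_sources("si", 1)
        d_i = net.add_source_drivers("si", -1, 0.01, 10.0)
        calibrate_drivers(net, d_e, d_i, target_rate=10.0,
                          ratio_inh_exc=4.0, probe_rate=300.0,
                          window_ms=1000.0, seed=0)
        int_e = net.driver_g_max[int(d_e[0])] * 5.0
        int_i = net.driver_g_max[int(d_i[0])] * 10.0
        assert int_i / int_e == pytest.approx(4.0, rel=1e-6)


class TestExcitability:
    def _net(self):
        net = Network("exc")
        net.add_population("p", 3, NeuronParams())
        net.add_sources("s", 8)
        drv = net.add_source_drivers("s", +1, 0.012, 5.0)
        for d in drv:
            for n in range(3):
                net.set_weight(int(d), n, 0.5)
        return net, drv

    def test_leaky_neuron_gets_larger_scale(self):
        net, _ = self._net()
        net.set_neuron_param(1, g_l=0.026)  # +30% leak
        res = calibrate_excitability(net, 10.0, input_rate=40.0,
                                     window_ms=1500.0, seed=0)
        assert res.scale[1] > res.scale[0]

    def test_rate_dispersion_reduced(self):
        net, drv = self._net()
        net.set_neuron_param(0, g_l=0.014)
        net.set_neuron_param(2, g_l=0.028)
        from spikesim.core import simulate
        from spikesim.stimuli import poisson_sources

        def rates(n):
            stim = poisson_sources(8, 40.0, 3000.0, seed=11)
            out = simulate(n, stim, 3000.0, seed=2)
            return out.rates([0, 1, 2], 3000.0)

        before = rates(net)
        calibrate_excitability(net, 10.0, input_rate=40.0,
                               window_ms=1500.0, seed=0)
        after = rates(net)
        assert after.std() < before.std() / 2


class TestAntennalLobe:
    def test_noise_free_al_needs_no_corrections(self):
        from spikesim.networks.antennal_lobe import build_antennal_lobe

        net, info = build_antennal_lobe(seed=0, q=1.0)
        w_before = net.weight_matrix().copy()
        res = calibrate_antennal_lobe(net, info, tol=0.25, max_iter=2,
                                      window_ms=500.0, seed=0)
        assert not info.helper_streams
        # lateral weights restored to their pre-calibration scale
        assert info.lateral_scale == 1.0
        assert np.allclose(net.weight_matrix(), w_before)

    def test_weak_neuron_recovers_toward_target(self):
        from spikesim.core import simulate
        from spikesim.networks.antennal_lobe import build_antennal_lobe

        net, info = build_antennal_lobe(seed=0, q=0.0)
        weak = int(info.pn_ids[0][0])
        # cripple one PN's input weights far below its siblings
        for d in info.rn_drivers[0]:
            net.set_weight(int(d), weak, 0.45)
        res = calibrate_antennal_lobe(net, info, tol=0.1, max_iter=6,
                                      window_ms=1000.0, seed=0)
        stim = info.uniform_stimulus(40.0, 1000.0, seed=5)
        out = simulate(net, stim, 1000.0, seed=6)
        r_weak = out.rates([weak], 1000.0)[0]
        siblings = [int(i) for i in info.pn_ids[0][1:]]
        r_sib = out.rates(siblings, 1000.0).mean()
        assert r_weak > 0.75 * r_sib
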