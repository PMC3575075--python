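"""Core integrator: closed-form checks, refractoriness, STP, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikesim.core import (Network, NeuronParams, SpikeData, STPParams,
                           conductance_course, simulate, step_membrane,
                           stp_efficacy)


def test_membrane_equilibrium_is_fixed_point(single_neuron):
    net, p = single_neuron
    res = simulate(net, None, 50.0, dt=0.01, seed=0, record_v=[0])
    assert np.allclose(res.traces[0], p.E_l, atol=1e-9)


def test_membrane_relaxation_matches_closed_form():
    """With zero conductance, V relaxes to E_l exponentially with tau_m."""
    p = NeuronParams(C_m=0.2, g_l=0.02, E_l=-70.0, V_th=0.0, V_reset=-70.0)
    tau_m = p.tau_m
    assert tau_m == 10.0
    V = np.array([p.E_l + 10.0])
    dt = 0.01
    zeros = np.zeros(1)
    arr = lambda x: np.array([x])
    for _ in range(int(10.0 / dt)):  # integrate 10 ms = one tau_m
        V = step_membrane(V, zeros, zeros, dt, arr(p.C_m), arr(p.g_l),
                          arr(p.E_l), arr(p.E_exc), arr(p.E_inh))
    expected = p.E_l + 10.0 * math.exp(-1.0)
    assert abs(V[0] - expected) / abs(expected) < 1e-6


def test_step_membrane_rejects_nonpositive_dt():
    with pytest.raises(ValueError):
        step_membrane(np.zeros(1), np.zeros(1), np.zeros(1), 0.0,
                      np.ones(1), np.ones(1), np.zeros(1), np.zeros(1),
                      np.zeros(1))


def test_free_running_rate_matches_one_over_tau_sum(single_neuron):
    """At the 1/e threshold the free-run frequency is 1/(tau_m+tau_refrac)."""
    net, p = single_neuron
    v_th = p.E_l - (p.E_l - p.V_reset) / math.e
    net.set_neuron_param(0, V_th=v_th)
    res = simulate(net, None, 10_000.0, dt=0.1, seed=0)
    rate = len(res.spikes) / 10.0  # Hz
    expected = 1000.0 / (p.tau_m + p.tau_refrac)
    assert abs(rate - expected) / expected < 0.01


def test_strong_input_fires_exactly_once_with_positive_latency():
    net = Network("one_shot")
    net.add_population("p", 1, NeuronParams(tau_refrac=5.0))
    net.add_sources("s", 1)
    d = net.add_source_drivers("s", +1, 0.15, 1.0)[0]  # strong, brief
    net.set_weight(d, 0, 1.0)
    res = simulate(net, SpikeData([5.0], [0]), 20.0, dt=0.1, seed=0)
    assert len(res.spikes) == 1
    assert res.spikes.times[0] > 5.0 + net.delay_ms  # latency >= axonal delay


def test_refractory_clamp_limits_spike_spacing(driven_neuron):
    net, d_e, _ = driven_neuron
    net.driver_g_max[d_e] = 0.5
    net.set_neuron_param(0, tau_refrac=3.0)
    stim = SpikeData(np.arange(2.0, 50.0, 1.0), np.zeros(48, dtype=int))
    res = simulate(net, stim, 60.0, dt=0.1, seed=0)
    assert len(res.spikes) > 3
    assert np.diff(res.spikes.times).min() >= 3.0 - 1e-9


def test_membrane_stays_within_reversal_bounds(driven_neuron):
    net, d_e, d_i = driven_neuron
    net.driver_g_max[d_e] = 0.3
    net.driver_g_max[d_i] = 0.3
    net.set_neuron_param(0, V_th=100.0)  # never spike
    stim = SpikeData.merge([
        SpikeData(np.arange(1.0, 90.0, 2.0), np.zeros(45, dtype=int)),
        SpikeData(np.arange(1.5, 90.0, 2.0), np.ones(45, dtype=int)),
    ])
    res = simulate(net, stim, 100.0, dt=0.1, seed=0, record_v=[0])
    p = net.neuron_param(0)
    assert res.traces[0].min() >= p.E_inh - 1e-9
    assert res.traces[0].max() <= p.E_exc + 1e-9


def test_simulation_is_bit_reproducible():
    net = Network("n")
    net.add_population("p", 5, NeuronParams(E_l=-60.0, V_th=-59.5))
    net.membrane_noise_sd = 0.5
    a = simulate(net, None, 500.0, dt=0.1, seed=7)
    b = simulate(net, None, 500.0, dt=0.1, seed=7)
    assert a.spikes == b.spikes


def test_unknown_stimulus_source_is_rejected(driven_neuron):
    net, *_ = driven_neuron
    with pytest.raises(ValueError, match="unknown source"):
        simulate(net, SpikeData([1.0], [99]), 10.0)


# ---------------------------------------------------------------------------
# conductance course


def test_conductance_course_closed_forms():
    assert conductance_course(1.0, 1.0, 5.0, np.array([]), 3.0) == 0.0
    g = conductance_course(1.0, 1.0, 5.0, np.array([0.0]), 5.0)
    assert abs(g - math.exp(-1.0)) < 1e-12
    # additive superposition with STP off
    g2 = conductance_course(1.0, 1.0, 5.0, np.array([0.0, 0.0]), 5.0)
    assert abs(g2 - 2 * g) < 1e-12


def test_engine_conductance_matches_analytic_course(driven_neuron):
    """The clock-driven conductance equals the closed form at step ends."""
    net, d_e, _ = driven_neuron
    net.set_neuron_param(0, V_th=100.0, g_l=1e-9)  # nearly pure integrator
    # infer conductance from the voltage derivative instead: simpler check
    # on the subthreshold trace against the ODE solution with analytic g
    stim_t = np.array([2.0, 7.0])
    res = simulate(net, SpikeData(stim_t, [0, 0]), 30.0, dt=0.01, seed=0,
                   record_v=[0])
    p = net.neuron_param(0)
    # integrate the reference ODE at fine resolution with analytic g(t)
    dt = 0.01
    V = p.E_l
    vs = []
    for k in range(res.trace_times.size):
        t = k * dt
        g = conductance_course(1.0, net.driver_g_max[d_e], 5.0,
                               stim_t + net.delay_ms, t)
        g_tot = p.g_l + g
        v_inf = (p.g_l * p.E_l + g * p.E_exc) / g_tot
        V = v_inf + (V - v_inf) * math.exp(-g_tot * dt / p.C_m)
        vs.append(V)
    assert np.allclose(res.traces[0], vs, atol=0.15)


# ---------------------------------------------------------------------------
# short-term plasticity


def test_stp_off_gives_unit_efficacies():
    eff = stp_efficacy(STPParams(), np.arange(5.0))
    assert np.all(eff == 1.0)


def test_depressing_first_spike_and_recovery_limit():
    stp = STPParams(mode="depressing", U_SE=0.5, tau_rec=100.0)
    assert stp_efficacy(stp, np.array([0.0]))[0] == 0.5
    # intervals much longer than tau_rec: full recovery, equal efficacies
    eff = stp_efficacy(stp, np.array([0.0, 5000.0, 10000.0]))
    assert np.allclose(eff, 0.5, atol=1e-6)


def test_depressing_is_strictly_decreasing_at_short_intervals():
    stp = STPParams(mode="depressing", U_SE=0.3, tau_rec=500.0)
    eff = stp_efficacy(stp, np.arange(0.0, 50.0, 5.0))
    assert np.all(np.diff(eff) < 0)


def test_facilitating_grows_then_recovers():
    stp = STPParams(mode="facilitating", U_SE=0.2, tau_facil=100.0)
    eff = stp_efficacy(stp, np.array([0.0, 5.0, 10.0]))
    assert eff[0] == pytest.approx(0.2)
    assert np.all(np.diff(eff) > 0)
    # a lone spike after a long pause is back at U_SE
    eff2 = stp_efficacy(stp, np.array([0.0, 10_000.0]))
    assert eff2[1] == pytest.approx(0.2, abs=1e-6)


@settings(derandomize=True, max_examples=25)
@given(u=st.floats(0.05, 0.95), tau=st.floats(20.0, 500.0),
       n=st.integers(2, 20))
def test_depressing_efficacies_bounded(u, tau, n):
    stp = STPParams(mode="depressing", U_SE=u, tau_rec=tau)
    eff = stp_efficacy(stp, np.cumsum(np.full(n, 7.0)))
    assert np.all(eff > 0) and np.all(eff <= u + 1e-12)


def test_online_stp_matches_batch_recursion(driven_neuron):
    """Internal-driver STP (online) agrees with the batch efficacy path."""
    stp = STPParams(mode="depressing", U_SE=0.5, tau_rec=80.0)
    # relay: source -> neuron A (fires 1:1) -> depressing driver -> neuron B
    net = Network("relay")
    net.add_population("a", 1, NeuronParams(tau_refrac=6.0))
    # readout neuron with a fast membrane so PSP amplitude tracks efficacy
    net.add_population("b", 1, NeuronParams(V_th=100.0, g_l=0.2))
    net.add_sources("s", 1)
    d_in = net.add_source_drivers("s", +1, 0.15, 1.0)[0]
    net.set_weight(d_in, 0, 1.0)
    d_ab = net.add_internal_drivers("a", +1, 0.01, 1.0, stp)[0]
    net.set_weight(d_ab, 1, 1.0)
    stim_t = np.array([5.0, 15.0, 25.0, 35.0])
    res = simulate(net, SpikeData(stim_t, [0, 0, 0, 0]), 60.0, dt=0.1, seed=0,
                   record_v=[1])
    a_spikes = res.spikes.times[res.spikes.units == 0]
    assert a_spikes.size == 4
    # B's PSP amplitudes shrink according to the batch recursion
    eff = stp_efficacy(stp, a_spikes)
    v, tt = res.traces[1], res.trace_times
    amps = []
    for t in a_spikes + net.delay_ms:
        base = v[(tt > t - 1.0) & (tt <= t)].min()
        amps.append(v[(tt > t) & (tt < t + 5.0)].max() - base)
    ratios = np.array(amps[1:]) / amps[0]
    assert np.allclose(ratios, eff[1:] / eff[0], atol=0.06)


def test_dt_convergence_on_balanced_network():
    """Halving dt changes the spike count of a BRN run by < 5%."""
    from spikesim.networks.brn import brn_stimulus, build_brn

    net, info = build_brn(seed=0, w_exc=0.29)
    stim = brn_stimulus(info, 2000.0, seed=3)
    n_coarse = len(simulate(net, stim, 2000.0, dt=0.1, seed=1).spikes)
    n_fine = len(simulate(net, stim, 2000.0, dt=0.05, seed=1).spikes)
    assert abs(n_fine - n_coarse) / n_coarse < 0.05
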