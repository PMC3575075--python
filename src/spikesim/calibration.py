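"""Calibration routines mapping target parameters onto a noisy substrate.

Analog fixed-pattern noise makes nominally identical neurons and drivers
behave differently.  The routines here measure each unit's response in
simulation and correct its individually settable knobs (leak bias, driver
strength, afferent weights) until the response is homogeneous:

* ``calibrate_tau_m`` exploits the 1/e trick: with the threshold placed at
  V_th = E_l - (E_l - V_reset)/e the neuron free-runs with period
  tau_m + tau_refrac, so the membrane time constant can be read off a
  spike count and corrected through g_l.
* ``calibrate_drivers`` equalizes synapse line drivers against a probe
  population, then fixes the inhibitory/excitatory strength ratio in
  conductance-integral terms (g_max * tau_fall).
* ``calibrate_excitability`` scales each neuron's afferent weight column so
  its rate under estimated in-network input statistics hits the target.
* ``calibrate_antennal_lobe`` homogenizes PN and LN responses per
  glomerulus with weight reduction, acyclic helper excitation, and extra
  input streams, mirroring a calibrate-once / run-many chip workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core import Network, NeuronParams, SpikeData, simulate
from .stimuli import poisson_sources

__all__ = [
    "CalibrationResult",
    "calibrate_tau_m",
    "calibrate_drivers",
    "calibrate_excitability",
    "calibrate_antennal_lobe",
]

DEFAULT_TOL = 0.10  # the global +-10% calibration tolerance


@dataclass
class CalibrationResult:
    scale: dict[int, float] = field(default_factory=dict)
    converged: dict[int, bool] = field(default_factory=dict)
    residual: dict[int, float] = field(default_factory=dict)
    iterations: int = 0
    flagged: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def n_converged(self) -> int:
        return sum(self.converged.values())

    def summary(self) -> str:
        n = len(self.converged)
        return (f"{self.n_converged}/{n} units converged in "
                f"{self.iterations} iterations; {len(self.flagged)} flagged")


def _free_run_probe(network: Network, neuron_ids) -> Network:
    """Synapse-free copy of selected neurons (drivers disabled, as during
    on-chip calibration).

    The 1/e protocol needs the reset well below rest; neurons whose
    configured V_reset coincides with E_l get a 10 mV probe reset (the
    inferred tau_m does not depend on the reset depth).
    """
    probe = Network("tau_probe")
    ids = [int(i) for i in neuron_ids]
    probe.add_population("probe", len(ids), NeuronParams())
    for k, nid in enumerate(ids):
        p = network.neuron_param(nid)
        if p.V_reset > p.E_l - 1.0:
            p = replace(p, V_reset=p.E_l - 10.0, V_th=min(p.V_th, p.E_l))
        probe._params[k] = p
    return probe


def calibrate_tau_m(network: Network, target_tau_m: float = 10.0, *,
                    tau_refrac: float = 1.0, tol: float = 0.05,
                    max_iter: int = 10, window_ms: float = 10_000.0,
                    dt: float = 0.1, neuron_ids=None,
                    apply: bool = True) -> CalibrationResult:
    """Calibrate per-neuron g_l so tau_m = C_m/g_l matches the target.

    The threshold is set to V_th = E_l - (E_l - V_reset)/e, which makes the
    free-running spike frequency 1/(tau_m + tau_refrac); tau_m is inferred
    from the measured rate and g_l is rescaled multiplicatively (steps
    clamped to x[0.5, 2]) until |tau_m - target| <= tol * target.  Neurons
    that stay silent even after one window extension, or fail to converge
    in ``max_iter`` sweeps, are flagged rather than silently kept.

    With ``apply=True`` the corrected g_l values are written back to the
    network (its V_th is left untouched).
    """
    if target_tau_m <= 0:
        raise ValueError("target_tau_m must be positive")
    neuron_ids = list(neuron_ids) if neuron_ids is not None else list(range(network.n_neurons))
    probe = _free_run_probe(network, neuron_ids)
    n = len(neuron_ids)
    for k in range(n):
        p = probe.neuron_param(k)
        v_th = p.E_l - (p.E_l - p.V_reset) / math.e
        probe.set_neuron_param(k, V_th=v_th, tau_refrac=tau_refrac)

    res = CalibrationResult()
    active = np.ones(n, dtype=bool)
    scale = np.ones(n)
    tau_hat = np.full(n, np.nan)
    for it in range(1, max_iter + 1):
        res.iterations = it
        result = simulate(probe, None, window_ms, dt=dt, seed=0)
        counts = np.bincount(result.spikes.units, minlength=n).astype(float)
        silent = active & (counts == 0)
        if silent.any():
            # one extended measurement for silent units
            result2 = simulate(probe, None, 2 * window_ms, dt=dt, seed=0)
            counts2 = np.bincount(result2.spikes.units, minlength=n).astype(float)
            for k in np.nonzero(silent)[0]:
                if counts2[k] == 0:
                    active[k] = False
                    res.flagged.append(neuron_ids[k])
                else:
                    counts[k] = counts2[k] / 2.0
        with np.errstate(divide="ignore"):
            period = np.where(counts > 0, window_ms / np.maximum(counts, 1), np.inf)
        tau_hat = period - tau_refrac
        err = np.abs(tau_hat - target_tau_m) / target_tau_m
        done = err <= tol
        pending = active & ~done
        if not pending.any():
            break
        for k in np.nonzero(pending)[0]:
            factor = float(np.clip(tau_hat[k] / target_tau_m, 0.5, 2.0))
            p = probe.neuron_param(k)
            probe.set_neuron_param(k, g_l=p.g_l * factor)
            scale[k] *= factor

    for k, nid in enumerate(neuron_ids):
        res.scale[nid] = float(scale[k])
        res.converged[nid] = bool(active[k] and
                                  abs(tau_hat[k] - target_tau_m) / target_tau_m <= tol)
        res.residual[nid] = float(abs(tau_hat[k] - target_tau_m) / target_tau_m)
        if active[k] and not res.converged[nid]:
            res.flagged.append(nid)
    if apply:
        for k, nid in enumerate(neuron_ids):
            p = network.neuron_param(nid)
            network.set_neuron_param(nid, g_l=p.g_l * float(scale[k]))
    return res


def measure_tau_m(network: Network, *, tau_refrac: float = 1.0,
                  window_ms: float = 10_000.0, dt: float = 0.1,
                  neuron_ids=None) -> np.ndarray:
    """Per-neuron tau_m from one free-running 1/e-threshold measurement."""
    neuron_ids = list(neuron_ids) if neuron_ids is not None else list(range(network.n_neurons))
    probe = _free_run_probe(network, neuron_ids)
    for k in range(len(neuron_ids)):
        p = probe.neuron_param(k)
        probe.set_neuron_param(k, V_th=p.E_l - (p.E_l - p.V_reset) / math.e,
                               tau_refrac=tau_refrac)
    result = simulate(probe, None, window_ms, dt=dt, seed=0)
    counts = np.bincount(result.spikes.units, minlength=len(neuron_ids)).astype(float)
    with np.errstate(divide="ignore"):
        period = np.where(counts > 0, window_ms / np.maximum(counts, 1), np.inf)
    return period - tau_refrac


# ---------------------------------------------------------------------------
# driver calibration


def _probe_rate_for_gmax(neuron_params: list[NeuronParams], g_max: float,
                         tau_fall: float, sign: int, probe_rate: float,
                         window_ms: float, dt: float, seed: int,
                         background: tuple[float, float, float] | None = None) -> float:
    """Mean rate of a probe population driven by one driver at ``g_max``.

    ``background`` = (g_max_bg, tau_fall_bg, rate_bg) adds a pre-calibrated
    excitatory background driver (used when probing inhibitory drivers).
    """
    probe = Network("driver_probe")
    probe.add_population("probe", len(neuron_params), NeuronParams())
    probe._params = list(neuron_params)
    probe.add_sources("stim", 1)
    d = probe.add_source_drivers("stim", sign, g_max, tau_fall)[0]
    for nid in range(len(neuron_params)):
        probe.set_weight(d, nid, 1.0)
    parts = [poisson_sources(1, probe_rate, window_ms, seed=seed)]
    if background is not None:
        g_bg, tau_bg, rate_bg = background
        probe.add_sources("bg", 1)
        db = probe.add_source_drivers("bg", +1, g_bg, tau_bg)[0]
        for nid in range(len(neuron_params)):
            probe.set_weight(db, nid, 1.0)
        parts.append(poisson_sources(1, rate_bg, window_ms, seed=seed + 1, offset=1))
    stim = SpikeData.merge(parts)
    out = simulate(probe, stim, window_ms, dt=dt, seed=seed)
    return len(out.spikes) / len(neuron_params) / (window_ms / 1000.0)


def _bisect_gmax(rate_fn, target: float, g0: float, increasing: bool,
                 tol: float, max_iter: int = 20) -> tuple[float, float, bool]:
    """Find g with rate_fn(g) ~= target by bracketing + bisection on log g.

    ``increasing`` states whether the rate grows with g (excitatory
    drivers) or falls (inhibitory ones).
    """
    lo = hi = g0
    r = rate_fn(g0)
    if abs(r - target) <= tol * target:
        return g0, r, True
    need_larger = (r < target) == increasing
    if need_larger:
        for _ in range(12):
            lo, hi = hi, hi * 4.0
            r = rate_fn(hi)
            if (r >= target) == increasing:
                break
        else:
            return hi, r, False
    else:
        for _ in range(12):
            hi, lo = lo, lo / 4.0
            r = rate_fn(lo)
            if (r < target) == increasing:
                break
        else:
            return lo, r, False
    g = g0
    for _ in range(max_iter):
        g = math.sqrt(lo * hi)
        r = rate_fn(g)
        if abs(r - target) <= tol * target:
            return g, r, True
        if (r < target) == increasing:
            lo = g
        else:
            hi = g
    return g, r, False


def calibrate_drivers(network: Network, exc_drivers, inh_drivers, *,
                      target_rate: float = 10.0, ratio_inh_exc: float = 4.0,
                      tol: float = DEFAULT_TOL, probe_rate: float = 300.0,
                      window_ms: float = 2000.0, dt: float = 0.1,
                      probe_neurons=None, seed: int = 0,
                      apply: bool = True) -> CalibrationResult:
    """Equalize line-driver strengths, then fix the inhibition ratio.

    Each excitatory driver's g_max is adjusted until a standard probe
    population, stimulated by that driver alone through a Poisson train at
    ``probe_rate``, fires at ``target_rate`` within +-tol.  Inhibitory
    drivers are calibrated against a pre-calibrated excitatory background
    that alone drives the probe above target.  Finally every inhibitory
    g_max is rescaled so its conductance integral g_max * tau_fall equals
    ``ratio_inh_exc`` times the median calibrated excitatory integral.
    """
    probe_ids = list(probe_neurons) if probe_neurons is not None \
        else list(range(network.n_neurons))
    params = [network.neuron_param(i) for i in probe_ids]
    res = CalibrationResult()

    exc_drivers = [int(d) for d in exc_drivers]
    inh_drivers = [int(d) for d in inh_drivers]
    for d in exc_drivers:
        g0 = network.driver_g_max[d]
        tau = network.driver_tau_fall[d]

        def rate_fn(g, _tau=tau):
            return _probe_rate_for_gmax(params, g, _tau, +1, probe_rate,
                                        window_ms, dt, seed)

        g, rate, ok = _bisect_gmax(rate_fn, target_rate, g0, True, tol)
        res.scale[d] = g / g0
        res.converged[d] = ok
        res.residual[d] = abs(rate - target_rate) / target_rate
        if not ok:
            res.flagged.append(d)
        if apply:
            network.driver_g_max[d] = g

    if exc_drivers:
        integrals = [network.driver_g_max[d] * network.driver_tau_fall[d]
                     for d in exc_drivers]
        ref_integral = float(np.median(integrals))
        g_bg = float(np.median([network.driver_g_max[d] for d in exc_drivers]))
        tau_bg = float(np.median([network.driver_tau_fall[d] for d in exc_drivers]))
    else:
        ref_integral, g_bg, tau_bg = 1e-3, 1e-3, 5.0
    bg = (2.0 * g_bg, tau_bg, probe_rate)  # strong background, ~2x target drive

    for d in inh_drivers:
        g0 = network.driver_g_max[d]
        tau = network.driver_tau_fall[d]

        def rate_fn(g, _tau=tau):
            return _probe_rate_for_gmax(params, g, _tau, -1, probe_rate,
                                        window_ms, dt, seed, background=bg)

        g, rate, ok = _bisect_gmax(rate_fn, target_rate, g0, False, tol)
        res.converged[d] = ok
        res.residual[d] = abs(rate - target_rate) / target_rate
        if not ok:
            res.flagged.append(d)
        # ratio step: fix the conductance integral relative to excitation
        g_ratio = ratio_inh_exc * ref_integral / tau
        res.scale[d] = g_ratio / g0
        if apply:
            network.driver_g_max[d] = g_ratio
    res.iterations = 1
    return res


# ---------------------------------------------------------------------------
# per-neuron excitability calibration


def calibrate_excitability(network: Network, target_rate: float, *,
                           input_rate: float, tol: float = DEFAULT_TOL,
                           max_iter: int = 12, window_ms: float = 2000.0,
                           dt: float = 0.1, neuron_ids=None, seed: int = 0,
                           apply: bool = True) -> CalibrationResult:
    """Scale each neuron's afferent weight column to hit the target rate.

    Each neuron is probed in isolation: its afferent drivers are retained
    but fed by independent Poisson trains at ``input_rate`` (the estimated
    per-input rate of the final network).  One multiplicative factor per
    neuron scales all afferent weights; factors that would push a weight
    past the ceiling of 1 are clipped and the neuron is flagged.
    """
    neuron_ids = list(neuron_ids) if neuron_ids is not None \
        else list(range(network.n_neurons))
    W = network.weight_matrix()
    res = CalibrationResult()
    for nid in neuron_ids:
        aff = np.nonzero(W[:, nid])[0]
        if aff.size == 0:
            res.converged[nid] = False
            res.flagged.append(nid)
            continue
        probe = Network("excit_probe")
        probe.add_population("probe", 1, network.neuron_param(nid))
        probe.add_sources("in", aff.size)
        stim_parts = []
        for k, d in enumerate(aff):
            dd = probe._add_driver("ext", k, network.driver_sign[d],
                                   network.driver_g_max[d],
                                   network.driver_tau_fall[d],
                                   network.driver_stp[d])
            probe.set_weight(dd, 0, float(W[d, nid]))
            stim_parts.append(poisson_sources(1, input_rate, window_ms,
                                              seed=seed + 7919 * int(d), offset=k))
        stim = SpikeData.merge(stim_parts)
        base_w = np.array([probe.get_weight(k, 0) for k in range(aff.size)])
        s_lo, s_hi = 1.0, 1.0
        s_max = 1.0 / base_w.max()

        def rate_at(s):
            for k in range(aff.size):
                probe.set_weight(k, 0, min(base_w[k] * s, 1.0))
            out = simulate(probe, stim, window_ms, dt=dt, seed=seed)
            return len(out.spikes) / (window_ms / 1000.0)

        r1 = rate_at(1.0)
        ok = abs(r1 - target_rate) <= tol * target_rate
        s = 1.0
        if not ok:
            # bracket
            if r1 < target_rate:
                s_hi = 1.0
                while s_hi < s_max and rate_at(min(s_hi * 2, s_max)) < target_rate:
                    s_hi = min(s_hi * 2, s_max)
                    if s_hi == s_max:
                        break
                s_lo, s_hi = s_hi / 2 if s_hi > 1 else 1.0, min(s_hi * 2, s_max)
            else:
                s_lo = 1.0
                while s_lo > 1e-3 and rate_at(s_lo / 2) > target_rate:
                    s_lo = s_lo / 2
                s_lo, s_hi = s_lo / 2, s_lo * 2 if s_lo < 1 else 1.0
            for _ in range(max_iter):
                s = math.sqrt(max(s_lo, 1e-6) * s_hi)
                r = rate_at(s)
                if abs(r - target_rate) <= tol * target_rate:
                    ok = True
                    break
                if r < target_rate:
                    s_lo = s
                else:
                    s_hi = s
            if not ok and s_hi >= s_max and rate_at(s_max) < target_rate:
                s = s_max
                res.notes.append(f"neuron {nid}: weight ceiling reached")
        res.scale[nid] = s
        res.converged[nid] = ok
        res.residual[nid] = abs(rate_at(s) - target_rate) / target_rate
        if not ok:
            res.flagged.append(nid)
        if apply:
            for d in aff:
                network.set_weight(int(d), nid, min(float(W[d, nid]) * s, 1.0))
    res.iterations = 1
    return res


# ---------------------------------------------------------------------------
# antennal-lobe calibration


def calibrate_antennal_lobe(net: Network, al, *, tol: float = DEFAULT_TOL,
                            max_iter: int = 6, reference_rate: float = 40.0,
                            window_ms: float = 1000.0, dt: float = 0.1,
                            seed: int = 0) -> CalibrationResult:
    """Homogenize PN (then LN) responses with lateral inhibition off.

    ``al`` is the :class:`~spikesim.networks.antennal_lobe.ALInfo` handle
    of the network.  The target rate is the median uncalibrated response to
    a uniform reference stimulus.  Units above target get their RN input
    weights reduced; units below target whose input weights are already at
    the ceiling receive helper excitation from strong PNs of the same
    glomerulus (checked to stay acyclic); an entirely weak glomerulus
    recruits one extra external input stream.
    """
    saved = al.set_lateral_scale(net, 0.0)
    res = CalibrationResult()
    helper_graph = nx.DiGraph()

    def present(run_seed):
        stim = al.uniform_stimulus(reference_rate, window_ms, seed=run_seed)
        return simulate(net, stim, window_ms, dt=dt, seed=run_seed)

    def unit_rates(result, ids):
        return result.rates(ids, window_ms)

    for layer in ("pn", "ln"):
        ids_by_glom = al.pn_ids if layer == "pn" else al.ln_ids
        all_ids = np.concatenate(ids_by_glom)
        out = present(seed)
        rates = unit_rates(out, all_ids)
        target = float(np.median(rates))
        res.notes.append(f"{layer} target rate {target:.2f} Hz")
        for it in range(max_iter):
            res.iterations += 1
            out = present(seed + it)
            rates = dict(zip(all_ids.tolist(), unit_rates(out, all_ids)))
            n_bad = 0
            for gi, ids in enumerate(ids_by_glom):
                glom_weak = all(rates[i] < (1 - tol) * target for i in ids)
                for nid in ids:
                    r = rates[nid]
                    if abs(r - target) <= tol * target:
                        continue
                    n_bad += 1
                    in_drivers = al.input_drivers(net, nid, layer)
                    ws = [net.get_weight(d, nid) for d in in_drivers]
                    if r > target:
                        f = max(target / max(r, 1e-9), 0.4)
                        for d, w in zip(in_drivers, ws):
                            net.set_weight(d, nid, max(w * f, 0.0))
                    else:
                        if max(ws, default=1.0) < 0.999:
                            f = min(target / max(r, 1e-9), 2.5)
                            for d, w in zip(in_drivers, ws):
                                net.set_weight(d, nid, min(w * f, 1.0))
                        elif layer == "pn" and not glom_weak:
                            donor = max(ids, key=lambda i: rates[i])
                            helper_graph.add_nodes_from([donor, nid])
                            if donor != nid and not nx.has_path(helper_graph, nid, donor):
                                d = net.drivers_of_neuron(donor)[0]
                                w_old = net.get_weight(d, nid)
                                net.set_weight(d, nid, min(w_old + 0.15, 1.0))
                                helper_graph.add_edge(donor, nid)
                                res.notes.append(f"helper PN {donor} -> PN {nid}")
                        elif glom_weak:
                            sid = al.add_helper_stream(net, gi, layer)
                            if sid is not None:
                                res.notes.append(f"extra input stream for glomerulus {gi}")
            if n_bad == 0:
                break
        out = present(seed + 999)
        rates = dict(zip(all_ids.tolist(), unit_rates(out, all_ids)))
        for nid in all_ids.tolist():
            ok = abs(rates[nid] - target) <= tol * target
            res.converged[nid] = ok
            res.residual[nid] = abs(rates[nid] - target) / max(target, 1e-9)
            if not ok:
                res.flagged.append(nid)
    assert nx.is_directed_acyclic_graph(helper_graph)
    al.set_lateral_scale(net, saved)
    return res
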