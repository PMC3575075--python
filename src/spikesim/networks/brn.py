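"""Balanced random network: asynchronous-irregular activity at desk scale.

A 125-neuron scale-down (factor 100 from the classic 12,500-neuron
version) of a sparsely connected excitatory/inhibitory network: 100
excitatory and 25 inhibitory neurons, stimulated by 100 excitatory and 25
inhibitory independent Poisson sources, every projection drawn Bernoulli
with p = 0.1, and inhibitory synaptic weights four times the excitatory
ones.  Excitatory efferents are short-term depressing, which prevents
self-reinforcing runaway at this small size.  The excitatory weight is the
single free knob, tuned so the network fires at a target mean rate
(~9 Hz); the irregularity (ISI CV ~ 1) and asynchrony (pairwise spike-count
correlation ~ 0) then emerge from the balance of excitation and inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Network, NeuronParams, STPParams, SpikeData, simulate
from ..stimuli import poisson_sources

__all__ = ["BRNInfo", "build_brn", "brn_stimulus", "tune_brn_weight", "run_brn"]

# network constants
N_E, N_I = 100, 25
N_P, N_Q = 100, 25
P_CONN = 0.1
RATIO_INH_EXC = 4.0
NU_EXT = 10.0  # Hz, Poisson source rate
G_UNIT = 0.02  # uS peak conductance of an excitatory driver at weight 1
TAU_SYN = 5.0  # ms conductance decay
W_EXC_DEFAULT = 0.29  # tuned for ~9 Hz mean rate at the default parameters

BRN_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-70.0, E_exc=0.0, E_inh=-80.0,
                          V_th=-55.0, V_reset=-70.0, tau_refrac=2.0)
BRN_STP = STPParams(mode="depressing", U_SE=0.4, tau_rec=150.0)


@dataclass
class BRNInfo:
    exc: np.ndarray
    inh: np.ndarray
    src_exc: np.ndarray
    src_inh: np.ndarray
    w_exc: float


def build_brn(seed: int = 0, *, w_exc: float = W_EXC_DEFAULT,
              stp: bool = True) -> tuple[Network, BRNInfo]:
    """Build the 125-neuron balanced random network.

    All eight projections (4 feedforward from the source populations onto
    both neuron populations, 4 recurrent including within-population ones)
    use connection probability 0.1.  Inhibitory drivers carry 4x the
    excitatory peak conductance; one weight value ``w_exc`` scales every
    synapse, so w_inh / w_exc = 4 holds exactly in conductance terms.
    """
    rng = np.random.default_rng(seed)
    net = Network("brn")
    exc = net.add_population("exc", N_E, BRN_PARAMS)
    inh = net.add_population("inh", N_I, BRN_PARAMS)
    src_e = net.add_sources("poisson_exc", N_P)
    src_i = net.add_sources("poisson_inh", N_Q)

    stp_exc = BRN_STP if stp else STPParams()
    d_exc = net.add_internal_drivers("exc", +1, G_UNIT, TAU_SYN, stp_exc)
    d_inh = net.add_internal_drivers("inh", -1, RATIO_INH_EXC * G_UNIT, TAU_SYN)
    d_src_e = net.add_source_drivers("poisson_exc", +1, G_UNIT, TAU_SYN)
    d_src_i = net.add_source_drivers("poisson_inh", -1, RATIO_INH_EXC * G_UNIT, TAU_SYN)

    all_ids = np.concatenate([exc, inh])
    for drivers in (d_exc, d_src_e):
        net.connect_drivers(drivers, all_ids, p=P_CONN, weight=w_exc, rng=rng,
                            allow_self=False)
    for drivers in (d_inh, d_src_i):
        net.connect_drivers(drivers, all_ids, p=P_CONN, weight=w_exc, rng=rng,
                            allow_self=False)
    return net, BRNInfo(exc, inh, src_e, src_i, w_exc)


def brn_stimulus(info: BRNInfo, T: float, seed: int = 0) -> SpikeData:
    """Poisson background: N_P + N_Q independent sources at NU_EXT Hz."""
    a = poisson_sources(N_P, NU_EXT, T, seed=seed, offset=int(info.src_exc[0]))
    b = poisson_sources(N_Q, NU_EXT, T, seed=seed + 1, offset=int(info.src_inh[0]))
    return SpikeData.merge([a, b])


def _mean_rate(net: Network, info: BRNInfo, T: float, seed: int,
               t_skip: float = 500.0) -> float:
    stim = brn_stimulus(info, T, seed=seed)
    out = simulate(net, stim, T, seed=seed)
    mask = out.spikes.times >= t_skip
    return float(mask.sum() / (N_E + N_I) / ((T - t_skip) / 1000.0))


def tune_brn_weight(target_rate: float = 9.0, *, seed: int = 0, tol: float = 0.05,
                    T: float = 3000.0, w_lo: float = 0.05, w_hi: float = 1.0,
                    max_iter: int = 12, stp: bool = True) -> float:
    """Bisect the excitatory weight until the mean network rate matches.

    Mirrors the way the reference software simulation picked its synaptic
    weight: the weight is not a model constant but defined by the target
    firing rate.
    """
    for it in range(max_iter):
        w = 0.5 * (w_lo + w_hi)
        net, info = build_brn(seed=seed, w_exc=w, stp=stp)
        r = _mean_rate(net, info, T, seed + 100 + it)
        if abs(r - target_rate) <= tol * target_rate:
            return w
        if r < target_rate:
            w_lo = w
        else:
            w_hi = w
    return w


def run_brn(T: float = 20_000.0, seed: int = 0, *, w_exc: float | None = None,
            target_rate: float = 9.0, stp: bool = True):
    """Tune (optionally), build, and simulate the BRN for T ms.

    Returns (result, info, net).
    """
    if w_exc is None:
        w_exc = tune_brn_weight(target_rate, seed=seed, stp=stp)
    net, info = build_brn(seed=seed, w_exc=w_exc, stp=stp)
    stim = brn_stimulus(info, T, seed=seed + 1)
    return simulate(net, stim, T, seed=seed + 2), info, net
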