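"""Soft winner-take-all ring network.

50 excitatory neurons on a ring share a common pool of 16 inhibitory
neurons.  Recurrent excitation between ring neighbors falls off with a
Gaussian profile (sd sigma_rec = 5 neurons, circular distance); the pool
receives from the ring (p = 0.6) and inhibits the whole ring uniformly
(all other projections p = 1).  Two stimulus cones centered on opposite
sides of the ring (neuron indices 13 and 38) deliver Poisson input through
Gaussian weight profiles (sd sigma_ext = 3 neurons, clipped beyond 3
sigma); each neuron inside a cone listens to five independent sources at
rate r.  When the two cone rates r1 and r2 differ, recurrent excitation
amplifies the stronger side while the shared pool suppresses the weaker
one: the half-ring rate curves cross where r2 = r1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Network, NeuronParams, SpikeData, simulate
from ..stimuli import poisson_sources

__all__ = ["SWTAInfo", "build_swta", "swta_stimulus", "run_swta", "sweep_r2"]

N_EXC, N_INH = 50, 16
SIGMA_REC = 5.0  # neurons
SIGMA_EXT = 3.0  # neurons, stimulus cone; clipped at 3 sigma
N_SRC_PER_NEURON = 5
MU_1, MU_2 = 13, 38  # cone centers (neuron indices)
P_EXC_INH = 0.6

SWTA_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-70.0, E_exc=0.0, E_inh=-80.0,
                           V_th=-55.0, V_reset=-70.0, tau_refrac=2.0)

TAU_SYN = 5.0
G_STIM = 0.006
G_EE = 0.0015
G_EI = 0.003
G_IE = 4.0 * G_EE  # inhibition four times the excitatory strength


def ring_distance(i: int, j: int, n: int = N_EXC) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


@dataclass
class SWTAInfo:
    exc: np.ndarray
    inh: np.ndarray
    cone1_sources: dict[int, np.ndarray]
    cone2_sources: dict[int, np.ndarray]


def _cone_neurons(mu: int) -> list[int]:
    return [i for i in range(N_EXC)
            if ring_distance(i, mu) <= 3 * SIGMA_EXT]


def build_swta(seed: int = 0) -> tuple[Network, SWTAInfo]:
    rng = np.random.default_rng(seed)
    net = Network("swta")
    exc = net.add_population("exc", N_EXC, SWTA_PARAMS)
    inh = net.add_population("inh", N_INH, SWTA_PARAMS)

    # one driver per ring neuron; its g_max covers the stronger of the two
    # efferent projections, per-synapse weights scale down from there
    g_axon = max(G_EE, G_EI)
    d_exc = net.add_internal_drivers("exc", +1, g_axon, TAU_SYN)
    d_inh = net.add_internal_drivers("inh", -1, G_IE, TAU_SYN)

    # ring recurrence: Gaussian profile of circular distance, p = 1, no autapse
    for i in range(N_EXC):
        for j in range(N_EXC):
            if i == j:
                continue
            d = ring_distance(i, j)
            w = (G_EE / g_axon) * float(np.exp(-d * d / (2 * SIGMA_REC ** 2)))
            if w > 1e-3:
                net.set_weight(int(d_exc[i]), int(exc[j]), w)
    # ring -> pool (p = 0.6, uniform weight)
    for i in range(N_EXC):
        for j in range(N_INH):
            if rng.random() < P_EXC_INH:
                net.set_weight(int(d_exc[i]), int(inh[j]), G_EI / g_axon)
    # pool -> ring and pool -> pool (p = 1, uniform)
    for i in range(N_INH):
        for j in range(N_EXC):
            net.set_weight(int(d_inh[i]), int(exc[j]), 1.0)

    cone1, cone2 = {}, {}
    for mu, cone, tag in ((MU_1, cone1, "cone1"), (MU_2, cone2, "cone2")):
        for i in _cone_neurons(mu):
            grp = f"{tag}_n{i}"
            src = net.add_sources(grp, N_SRC_PER_NEURON)
            w = float(np.exp(-ring_distance(i, mu) ** 2 / (2 * SIGMA_EXT ** 2)))
            drv = net.add_source_drivers(grp, +1, G_STIM, TAU_SYN)
            for d in drv:
                net.set_weight(int(d), int(exc[i]), w)
            cone[i] = src
    return net, SWTAInfo(exc, inh, cone1, cone2)


def swta_stimulus(info: SWTAInfo, r1: float, r2: float, T: float,
                  seed: int = 0) -> SpikeData:
    """Independent Poisson trains for both cones at rates r1 / r2 Hz."""
    parts = []
    k = 0
    for cone, r in ((info.cone1_sources, r1), (info.cone2_sources, r2)):
        for i, src in sorted(cone.items()):
            if r > 0:
                parts.append(poisson_sources(len(src), r, T, seed=seed * 7919 + k,
                                             offset=int(src[0])))
            k += 1
    return SpikeData.merge(parts)


def halves(info: SWTAInfo) -> tuple[np.ndarray, np.ndarray]:
    """The two half-rings around the cone centers."""
    h1 = np.array([i for i in range(N_EXC) if ring_distance(i, MU_1) <= 12])
    h2 = np.array([i for i in range(N_EXC) if ring_distance(i, MU_2) <= 12])
    return info.exc[h1], info.exc[h2]


def run_swta(net: Network, info: SWTAInfo, r1: float, r2: float, *,
             T: float = 2000.0, seed: int = 0):
    stim = swta_stimulus(info, r1, r2, T, seed=seed)
    return simulate(net, stim, T, seed=seed + 1)


def sweep_r2(r2_values, *, r1: float = 50.0, n_runs: int = 10,
             T: float = 2000.0, seed: int = 0, build_seed: int = 0):
    """Mean half-ring rates for each r2 (averaged over ``n_runs`` seeds).

    Returns (r2_values, rates_half1, rates_half2).
    """
    net, info = build_swta(seed=build_seed)
    h1, h2 = halves(info)
    out1, out2 = [], []
    for r2 in r2_values:
        acc1 = acc2 = 0.0
        for run in range(n_runs):
            res = run_swta(net, info, r1, float(r2), T=T,
                           seed=seed + 1000 * run + int(r2))
            n1 = np.isin(res.spikes.units, h1).sum()
            n2 = np.isin(res.spikes.units, h2).sum()
            acc1 += n1 / h1.size / (T / 1000.0)
            acc2 += n2 / h2.size / (T / 1000.0)
        out1.append(acc1 / n_runs)
        out2.append(acc2 / n_runs)
    return np.asarray(r2_values, dtype=float), np.asarray(out1), np.asarray(out2)


def crossing_point(r2, rates1, rates2) -> float:
    """r2 at which the two half-ring rate curves intersect (interpolated)."""
    d = np.asarray(rates2) - np.asarray(rates1)
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("curves do not cross on the sweep range")
    k = int(sign_change[0])
    x0, x1 = r2[k], r2[k + 1]
    y0, y1 = d[k], d[k + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
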