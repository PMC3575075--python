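"""Synfire chain with feedforward inhibition.

Groups of regular-spiking (RS, excitatory) and fast-spiking (FS,
inhibitory) neurons are chained feedforward: the RS population of group i
projects onto both the RS and FS populations of group i+1, while each FS
population inhibits the RS cells of its own group.  Every neuron receives
a fixed number of randomly chosen inputs from each presynaptic population.
A synchronous spike volley ("pulse packet", parametrized by spikes per
source ``a`` and temporal spread ``sigma``) either stabilizes toward the
propagation fixed point near (sigma, a) = (0.1 ms, 1) as it travels, or is
extinguished toward (0, 0); feedforward inhibition sharpens the boundary
(separatrix) between the two regimes.

Variants: ``original`` (groups of 100 RS + 25 FS), ``loop`` (small groups
of 8+8 closed into a ring), ``filter`` (3 groups of 45 RS + 18 FS fitting
one chip).  The missing background drive of the full-size original model
is compensated, as on the chip, by a raised resting potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..core import Network, NeuronParams, SpikeData, simulate
from ..stimuli import PulsePacket, pulse_packet

__all__ = ["SynfireInfo", "build_synfire", "synfire_stimulus", "run_packet"]

SYNFIRE_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-62.0, E_exc=0.0,
                              E_inh=-80.0, V_th=-55.0, V_reset=-70.0,
                              tau_refrac=2.0)
# FS cells are slightly more excitable so feedforward inhibition engages
# before weak, broad packets can regroup
FS_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-62.0, E_exc=0.0,
                         E_inh=-80.0, V_th=-56.5, V_reset=-70.0,
                         tau_refrac=2.0)

# synaptic constants (uS, ms); in-degrees per the fixed fan-in rule
G_EXC = 0.0007
G_INH = 0.0045
TAU_EXC = 1.5
TAU_INH = 8.0
K_RS = 60  # inputs each neuron draws from the previous RS population
K_FS = 25  # inputs each RS draws from its local FS population

_VARIANT_SIZES = {"original": (100, 25), "loop": (8, 8), "filter": (45, 18)}

# Loop variant: twelve 8+8 groups fill the 192-neuron substrate; the
# membrane is sped up (g_l doubled) and inhibition shortened so neurons
# recover before the packet returns (~23 ms cycle).
LOOP_N_GROUPS = 12
LOOP_G_L = 0.04
LOOP_TAU_INH = 4.0


@dataclass
class SynfireInfo:
    variant: str
    n_groups: int
    rs_groups: list[np.ndarray]
    fs_groups: list[np.ndarray]
    stim_sources: np.ndarray


def build_synfire(variant: str = "original", n_groups: int = 4, seed: int = 0,
                  *, n_rs: int | None = None, n_fs: int | None = None,
                  k_rs: int = K_RS, k_fs: int = K_FS,
                  w: float = 1.0) -> tuple[Network, SynfireInfo]:
    """Assemble the chain; ``loop`` closes the last group onto the first.

    In-degrees are clipped to the available population sizes for the small
    variants.  The stimulus population (as many external sources as one RS
    group) is wired onto group 0 exactly like an RS group.
    """
    if variant not in _VARIANT_SIZES:
        raise ValueError(f"unknown variant {variant!r}")
    default_rs, default_fs = _VARIANT_SIZES[variant]
    n_rs = n_rs or default_rs
    n_fs = n_fs or default_fs
    if variant == "filter":
        n_groups = 3
    elif variant == "loop":
        n_groups = LOOP_N_GROUPS
    rng = np.random.default_rng(seed)
    net = Network(f"synfire_{variant}")

    rs_params, fs_params = SYNFIRE_PARAMS, FS_PARAMS
    tau_inh = TAU_INH
    if variant == "loop":
        rs_params = replace(rs_params, g_l=LOOP_G_L)
        fs_params = replace(fs_params, g_l=LOOP_G_L)
        tau_inh = LOOP_TAU_INH

    rs_groups, fs_groups = [], []
    d_rs, d_fs = [], []
    k_rs_eff = min(k_rs, n_rs)
    k_fs_eff = min(k_fs, n_fs)
    # smaller groups keep the same total conductance per packet
    g_exc = G_EXC * (K_RS / k_rs_eff)
    g_inh = G_INH * (K_FS / k_fs_eff)
    for g in range(n_groups):
        rs = net.add_population(f"rs{g}", n_rs, rs_params)
        fs = net.add_population(f"fs{g}", n_fs, fs_params)
        rs_groups.append(rs)
        fs_groups.append(fs)
        d_rs.append(net.add_internal_drivers(f"rs{g}", +1, g_exc, TAU_EXC))
        d_fs.append(net.add_internal_drivers(f"fs{g}", -1, g_inh, tau_inh))

    stim = net.add_sources("stim", n_rs)
    d_stim = net.add_source_drivers("stim", +1, g_exc, TAU_EXC)
    pairs = [(d_stim, 0)] + [(d_rs[g], g + 1) for g in range(n_groups - 1)]
    if variant == "loop":
        pairs.append((d_rs[n_groups - 1], 0))
    for drivers, tgt in pairs:
        net.connect_drivers(drivers, rs_groups[tgt], in_degree=k_rs_eff,
                            weight=w, rng=rng)
        net.connect_drivers(drivers, fs_groups[tgt], in_degree=k_rs_eff,
                            weight=w, rng=rng)
    for g in range(n_groups):
        net.connect_drivers(d_fs[g], rs_groups[g], in_degree=k_fs_eff,
                            weight=w, rng=rng)
    return net, SynfireInfo(variant, n_groups, rs_groups, fs_groups, stim)


def synfire_stimulus(info: SynfireInfo, a: int, sigma: float,
                     t_center: float = 20.0, seed: int = 0) -> SpikeData:
    pp = PulsePacket(a=a, sigma=sigma, t_center=t_center,
                     n_sources=len(info.stim_sources))
    return pulse_packet(pp, seed=seed, offset=int(info.stim_sources[0]))


def run_packet(net: Network, info: SynfireInfo, a: int, sigma: float, *,
               T: float = 200.0, seed: int = 0, dt: float = 0.1):
    """Stimulate with one (a, sigma) packet and simulate for T ms."""
    stim = synfire_stimulus(info, a, sigma, seed=seed)
    return simulate(net, stim, T, dt=dt, seed=seed + 1)


def state_space_sweep(net: Network, info: SynfireInfo, a_values, sigma_values,
                      *, n_seeds: int = 3, measure_group: int | None = None,
                      threshold: float = 0.5, T: float = 150.0, seed: int = 0):
    """Map the packet state space: stimulate on an (a, sigma) grid and
    measure the packet arriving at ``measure_group``.

    Classification: *propagating* when the measured activity per neuron is
    at least ``threshold`` spikes.  Returns a pandas DataFrame with one
    row per (a, sigma, seed): realized output (a, sigma) and the label.
    """
    import pandas as pd

    from ..metrics import measure_packets

    g = measure_group if measure_group is not None else info.n_groups - 1
    rows = []
    for a in a_values:
        for sigma in sigma_values:
            for k in range(n_seeds):
                out = run_packet(net, info, int(a), float(sigma), T=T,
                                 seed=seed + 1000 * k + 17 * int(a))
                ms = measure_packets(out.spikes, info.rs_groups[g], group_index=g)
                best = max(ms, key=lambda m: m.n_spikes)
                rows.append({"a_stim": int(a), "sigma_stim": float(sigma),
                             "seed": k, "a_out": best.a,
                             "sigma_out": best.sigma,
                             "propagating": bool(best.a >= threshold)})
    return pd.DataFrame(rows)
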