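"""Insect antennal-lobe model: channel decorrelation by lateral inhibition.

Ten glomeruli, each bundling 6 receptor-neuron (RN) input streams that
project all-to-all onto 7 projection neurons (PNs), which drive 3 local
inhibitory neurons (LNs).  LNs send uniform inhibitory projections to the
PNs of all *other* glomeruli.  Odor-like stimuli are vectors of RN rates
(one rate per glomerulus); correlation between channels is reduced at the
PN output because each glomerulus's LN inhibition subtracts the common
activity of the others.  The strength of the lateral inhibition is a
single factor q in [0, 1]: q = 0 leaves channel correlations untouched,
q = 1 removes most of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import Network, NeuronParams, SpikeData, simulate
from ..stimuli import gamma_process

__all__ = ["ALInfo", "build_antennal_lobe", "run_al_patterns"]

N_GLOM = 10
N_RN, N_PN, N_LN = 6, 7, 3
GAMMA_ORDER = 5

AL_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-70.0, E_exc=0.0, E_inh=-80.0,
                         V_th=-55.0, V_reset=-70.0, tau_refrac=2.0)

TAU_SYN = 5.0
G_RN = 0.006     # RN -> PN drive
G_PN = 0.004     # PN -> LN drive
G_LAT = 0.02     # LN -> PN lateral inhibition at q = 1, weight 1


@dataclass
class ALInfo:
    pn_ids: list[np.ndarray]
    ln_ids: list[np.ndarray]
    rn_sources: list[np.ndarray]
    rn_drivers: list[np.ndarray]
    pn_drivers: list[np.ndarray]
    lateral_synapses: list[tuple[int, int, float]]  # (driver, neuron, base w)
    lateral_scale: float = 1.0
    helper_streams: list[tuple[int, int, str]] = field(default_factory=list)
    # (glomerulus, source id, layer)

    def set_lateral_scale(self, net: Network, q: float) -> float:
        """Scale all inter-glomerular inhibitory weights by q; returns the
        previous scale."""
        prev = self.lateral_scale
        for d, n, w in self.lateral_synapses:
            net.set_weight(d, n, w * q)
        self.lateral_scale = q
        return prev

    def input_drivers(self, net: Network, nid: int, layer: str) -> list[int]:
        """Drivers carrying feedforward input to one PN or LN."""
        gi = self.glomerulus_of(nid)
        if layer == "pn":
            drivers = [int(d) for d in self.rn_drivers[gi]]
            drivers += [int(net.drivers_of_source(sid)[0])
                        for g, sid, lay in self.helper_streams
                        if g == gi and lay == "pn"]
            return [d for d in drivers if net.get_weight(d, nid) > 0]
        return [int(d) for d in self.pn_drivers[gi]
                if net.get_weight(int(d), nid) > 0]

    def glomerulus_of(self, nid: int) -> int:
        for gi in range(len(self.pn_ids)):
            if nid in self.pn_ids[gi] or nid in self.ln_ids[gi]:
                return gi
        raise KeyError(nid)

    def add_helper_stream(self, net: Network, gi: int, layer: str):
        """Recruit one extra external input stream for a weak glomerulus."""
        existing = [h for h in self.helper_streams if h[0] == gi and h[2] == layer]
        if len(existing) >= 2:
            return None
        name = f"helper_g{gi}_{layer}{len(existing)}"
        sid = int(net.add_sources(name, 1)[0])
        d = net.add_source_drivers(name, +1, G_RN, TAU_SYN)[0]
        ids = self.pn_ids[gi] if layer == "pn" else self.ln_ids[gi]
        for nid in ids:
            net.set_weight(int(d), int(nid), 0.5)
        self.helper_streams.append((gi, sid, layer))
        return sid

    def uniform_stimulus(self, rate: float, T: float, seed: int = 0) -> SpikeData:
        """All RN streams (and helper streams) at one reference rate."""
        rates = np.full(N_GLOM, rate)
        return self.pattern_stimulus(rates, T, seed=seed)

    def pattern_stimulus(self, rates: np.ndarray, T: float, seed: int = 0) -> SpikeData:
        """Gamma-process (order 5) spike trains: glomerulus i's RNs (and any
        helper streams) fire at rates[i]."""
        parts = []
        for gi in range(N_GLOM):
            parts.append(gamma_process(float(rates[gi]), GAMMA_ORDER, T,
                                       seed=seed + 101 * gi, n=N_RN,
                                       offset=int(self.rn_sources[gi][0])))
        for k, (gi, sid, _layer) in enumerate(self.helper_streams):
            parts.append(gamma_process(float(rates[gi]), GAMMA_ORDER, T,
                                       seed=seed + 7001 + k, n=1, offset=sid))
        return SpikeData.merge(parts)


def build_antennal_lobe(n_glomeruli: int = N_GLOM, seed: int = 0,
                        q: float = 1.0) -> tuple[Network, ALInfo]:
    """Assemble the AL; ``q`` scales the inter-glomerular inhibition."""
    if n_glomeruli != N_GLOM:
        raise ValueError("the model is laid out for 10 glomeruli")
    net = Network("antennal_lobe")
    pn_ids, ln_ids, rn_sources, rn_drivers, pn_drivers, ln_drivers = \
        [], [], [], [], [], []
    for gi in range(n_glomeruli):
        pn_ids.append(net.add_population(f"pn{gi}", N_PN, AL_PARAMS))
        ln_ids.append(net.add_population(f"ln{gi}", N_LN, AL_PARAMS))
    for gi in range(n_glomeruli):
        rn_sources.append(net.add_sources(f"rn{gi}", N_RN))
        rn_drivers.append(net.add_source_drivers(f"rn{gi}", +1, G_RN, TAU_SYN))
        pn_drivers.append(net.add_internal_drivers(f"pn{gi}", +1, G_PN, TAU_SYN))
        ln_drivers.append(net.add_internal_drivers(f"ln{gi}", -1, G_LAT, TAU_SYN))
    lateral = []
    for gi in range(n_glomeruli):
        # RN -> PN all-to-all within the glomerulus
        for d in rn_drivers[gi]:
            for nid in pn_ids[gi]:
                net.set_weight(int(d), int(nid), 1.0)
        # PN -> LN within the glomerulus
        for d in pn_drivers[gi]:
            for nid in ln_ids[gi]:
                net.set_weight(int(d), int(nid), 1.0)
        # LN -> PNs of all other glomeruli, uniform weight
        for d in ln_drivers[gi]:
            for gj in range(n_glomeruli):
                if gj == gi:
                    continue
                for nid in pn_ids[gj]:
                    lateral.append((int(d), int(nid), 1.0))
                    net.set_weight(int(d), int(nid), q)
    info = ALInfo(pn_ids, ln_ids, rn_sources, rn_drivers, pn_drivers, lateral,
                  lateral_scale=q)
    return net, info


def run_al_patterns(net: Network, info: ALInfo, rate_matrix: np.ndarray, *,
                    duration: float = 1000.0, seed: int = 0,
                    dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Present each rate vector for ``duration`` ms; return per-glomerulus
    input (RN) and output (mean PN) rates, shape (n_patterns, n_glomeruli)."""
    n_patterns = rate_matrix.shape[0]
    pn_rates = np.zeros((n_patterns, N_GLOM))
    for k in range(n_patterns):
        stim = info.pattern_stimulus(rate_matrix[k], duration, seed=seed + 13 * k)
        out = simulate(net, stim, duration, dt=dt, seed=seed + 13 * k + 1)
        for gi in range(N_GLOM):
            pn_rates[k, gi] = out.rates(info.pn_ids[gi], duration).mean()
    return rate_matrix.copy(), pn_rates
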