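"""Cortical layer 2/3 attractor memory model (hypercolumns / minicolumns).

Hypercolumns are divided into minicolumns of pyramidal, RSNP (regular
spiking non-pyramidal, inhibitory) and basket cells.  A *pattern*
(attractor) is one minicolumn per hypercolumn; patterns are orthogonal, so
their number equals the minicolumns per hypercolumn.  Mutual excitation
between the pyramidal cells of a pattern (within and across hypercolumns)
sustains an elevated "UP" state once ignited; basket cells enforce a soft
WTA among the minicolumns of each hypercolumn, and RSNP cells, driven by
the pyramidal cells of *other* patterns, inhibit their own minicolumn's
pyramidal cells, implementing global pattern competition.  Short-term
depression of the pyramidal synapses (standing in for the spike-frequency
adaptation the substrate lacks) wears active patterns down, so the network
spontaneously alternates between attractors under diffuse Poisson drive,
and a partial "layer 4" cue can ignite (complete) a full pattern.

The scaled configuration (4 hypercolumns x 3 minicolumns of 13 pyramidal
+ 2 RSNP cells, plus one merged 2-cell basket population per hypercolumn,
188 neurons total) fits the 192-neuron substrate; the original
configuration (9 x 9 minicolumns of 30 + 2 + 1) totals 2673 neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Network, NeuronParams, STPParams, SpikeData, simulate
from ..stimuli import poisson_sources

__all__ = ["AttractorInfo", "build_attractor", "attractor_background",
           "run_attractor"]

ATTR_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-70.0, E_exc=0.0,
                           E_inh=-80.0, V_th=-55.0, V_reset=-70.0,
                           tau_refrac=2.0)
# basket and RSNP cells sit closer to threshold so the WTA inhibition
# engages even at moderate pyramidal rates
INTERNEURON_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-63.0, E_exc=0.0,
                                  E_inh=-80.0, V_th=-56.0, V_reset=-70.0,
                                  tau_refrac=2.0)
# slow depression of pyramidal efferents wears active patterns down
PYR_STP = STPParams(mode="depressing", U_SE=0.15, tau_rec=500.0)

TAU_EXC = 5.0
TAU_INH = 8.0
G_PYR = 0.005       # pyramidal axon peak conductance
G_BASKET = 0.015
G_RSNP = 0.05
G_NOISE = 0.004
G_L4 = 0.006
W_PP_LOCAL = 1.0    # pyr -> pyr same minicolumn
W_PP_PATTERN = 0.7  # pyr -> pyr other minicolumns of the pattern
W_PB = 0.6          # pyr -> basket (own hypercolumn)
W_PR = 1.0          # pyr -> RSNP of foreign-pattern minicolumns
N_NOISE_SOURCES = 24
NOISE_IN_DEGREE = 4
NOISE_RATE = 35.0  # Hz per source


@dataclass
class AttractorInfo:
    n_hc: int
    n_mc: int
    pyr: list[list[np.ndarray]]   # [hc][mc] pyramidal ids
    rsnp: list[list[np.ndarray]]
    basket: list[np.ndarray]      # [hc] merged basket population
    noise_sources: np.ndarray
    l4_sources: list[list[np.ndarray]]  # [hc][mc] one L4 source per minicolumn

    def pattern_pyr(self, p: int) -> np.ndarray:
        """All pyramidal cells of pattern p (minicolumn p of every HC)."""
        return np.concatenate([self.pyr[h][p] for h in range(self.n_hc)])

    @property
    def patterns(self) -> list[np.ndarray]:
        return [self.pattern_pyr(p) for p in range(self.n_mc)]


def build_attractor(n_hypercolumns: int = 4, n_minicolumns: int = 3,
                    n_pyr: int = 13, n_rsnp: int = 2, n_basket: int = 2,
                    seed: int = 0) -> tuple[Network, AttractorInfo]:
    """Assemble the scaled attractor network (defaults fit 192 neurons).

    Projection probabilities are 1 within the small receptive fields (the
    scaled population sizes put every projection at its maximum fan-in, so
    density is expressed through the synaptic weights instead, following
    the constant-average-fan-in scaling rule).
    """
    rng = np.random.default_rng(seed)
    net = Network("attractor")
    pyr, rsnp, basket, l4 = [], [], [], []
    d_pyr, d_rsnp, d_basket = [], [], []
    for h in range(n_hypercolumns):
        pyr.append([]); rsnp.append([]); l4.append([])
        d_pyr.append([]); d_rsnp.append([])
        for m in range(n_minicolumns):
            pyr[h].append(net.add_population(f"pyr_h{h}m{m}", n_pyr, ATTR_PARAMS))
            rsnp[h].append(net.add_population(f"rsnp_h{h}m{m}", n_rsnp, INTERNEURON_PARAMS))
        basket.append(net.add_population(f"basket_h{h}", n_basket, INTERNEURON_PARAMS))
    for h in range(n_hypercolumns):
        for m in range(n_minicolumns):
            d_pyr[h].append(net.add_internal_drivers(f"pyr_h{h}m{m}", +1,
                                                     G_PYR, TAU_EXC, PYR_STP))
            d_rsnp[h].append(net.add_internal_drivers(f"rsnp_h{h}m{m}", -1,
                                                      G_RSNP, TAU_INH))
        d_basket.append(net.add_internal_drivers(f"basket_h{h}", -1,
                                                 G_BASKET, TAU_INH))

    for h in range(n_hypercolumns):
        for m in range(n_minicolumns):
            # pyr -> pyr within the minicolumn
            for d in d_pyr[h][m]:
                for nid in pyr[h][m]:
                    if net.driver_source_id[int(d)] != int(nid):
                        net.set_weight(int(d), int(nid), W_PP_LOCAL)
            # pyr -> pyr of the same pattern in other hypercolumns
            for h2 in range(n_hypercolumns):
                if h2 == h:
                    continue
                for d in d_pyr[h][m]:
                    for nid in pyr[h2][m]:
                        net.set_weight(int(d), int(nid), W_PP_PATTERN)
            # pyr -> basket of the own hypercolumn
            for d in d_pyr[h][m]:
                for nid in basket[h]:
                    net.set_weight(int(d), int(nid), W_PB)
            # pyr -> RSNP of minicolumns belonging to other patterns
            for h2 in range(n_hypercolumns):
                for m2 in range(n_minicolumns):
                    if m2 == m:
                        continue
                    for d in d_pyr[h][m]:
                        for nid in rsnp[h2][m2]:
                            net.set_weight(int(d), int(nid), W_PR)
            # RSNP -> pyr of the own minicolumn
            for d in d_rsnp[h][m]:
                for nid in pyr[h][m]:
                    net.set_weight(int(d), int(nid), 1.0)
        # basket -> all pyr of the own hypercolumn
        for d in d_basket[h]:
            for m in range(n_minicolumns):
                for nid in pyr[h][m]:
                    net.set_weight(int(d), int(nid), 1.0)

    noise = net.add_sources("noise", N_NOISE_SOURCES)
    d_noise = net.add_source_drivers("noise", +1, G_NOISE, TAU_EXC)
    all_pyr = np.concatenate([pyr[h][m] for h in range(n_hypercolumns)
                              for m in range(n_minicolumns)])
    net.connect_drivers(d_noise, all_pyr, in_degree=NOISE_IN_DEGREE,
                        weight=1.0, rng=rng)

    l4_sources = []
    for h in range(n_hypercolumns):
        l4_sources.append([])
        for m in range(n_minicolumns):
            src = net.add_sources(f"l4_h{h}m{m}", 1)
            d = net.add_source_drivers(f"l4_h{h}m{m}", +1, G_L4, TAU_EXC)[0]
            for nid in pyr[h][m]:
                net.set_weight(int(d), int(nid), 1.0)
            l4_sources[h].append(src)

    info = AttractorInfo(n_hypercolumns, n_minicolumns, pyr, rsnp, basket,
                         noise, l4_sources)
    return net, info


def attractor_background(info: AttractorInfo, T: float, seed: int = 0,
                         rate: float | None = None) -> SpikeData:
    rate = NOISE_RATE if rate is None else rate
    return poisson_sources(len(info.noise_sources), rate, T, seed=seed,
                           offset=int(info.noise_sources[0]))


def l4_stimulus(info: AttractorInfo, pattern: int, n_minicolumns: int,
                T: float, rate: float = 120.0, seed: int = 0,
                t0: float = 0.0) -> SpikeData:
    """L4 cue: Poisson drive to the first ``n_minicolumns`` minicolumns of
    the given pattern."""
    parts = []
    for h in range(min(n_minicolumns, info.n_hc)):
        sid = int(info.l4_sources[h][pattern][0])
        p = poisson_sources(1, rate, T, seed=seed + h, offset=sid)
        parts.append(p.shift(t0))
    return SpikeData.merge(parts)


def run_attractor(T: float = 5000.0, seed: int = 0, *,
                  l4_pattern: int | None = None, l4_minicolumns: int = 0,
                  record_v: tuple = ()):
    """Build and run the scaled attractor network under diffuse noise."""
    net, info = build_attractor(seed=seed)
    stim = attractor_background(info, T, seed=seed + 1)
    if l4_pattern is not None and l4_minicolumns > 0:
        stim = SpikeData.merge([stim, l4_stimulus(info, l4_pattern,
                                                  l4_minicolumns, T,
                                                  seed=seed + 2)])
    out = simulate(net, stim, T, seed=seed + 3, record_v=record_v)
    return out, info, net
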