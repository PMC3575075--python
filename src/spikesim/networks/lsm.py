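"""Liquid state machine: a recurrent reservoir read out by a tempotron.

The liquid is a 191-neuron recurrent network (80:20 excitatory to
inhibitory) driven by 32 excitatory and 32 inhibitory spike sources; every
liquid neuron receives exactly 4 inputs from each source group.  One
neuron is left over for the readout, a tempotron trained to report which
of two equal-rate template spike trains produced the segment that occupied
a given 50 ms window of the input stream.  Because the decision window
contains only the liquid's *echo* of earlier segments, classification
accuracy probes the liquid's fading memory: one window back is
recoverable, segments further in the past fall to chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Network, NeuronParams, SpikeData, simulate
from ..stimuli import lsm_stream, lsm_templates
from ..tempotron import TempotronConfig, evaluate, train

__all__ = ["LSMInfo", "build_lsm", "lsm_experiment", "liquid_windows"]

N_LIQUID = 191
N_EXC = 153  # 80:20 split of 191
N_INH = 38
N_SRC = 32  # per sign
SRC_FAN_IN = 4  # inputs per neuron from each source group
SEGMENT_MS = 50.0
TEMPLATE_RATE = 25.0  # Hz per source channel
TEMPLATE_SLICES = 4   # template length in segments; window k uses slice k mod 4

LSM_PARAMS = NeuronParams(C_m=0.2, g_l=0.02, E_l=-65.0, E_exc=0.0, E_inh=-80.0,
                          V_th=-55.0, V_reset=-70.0, tau_refrac=2.0)

# the input synapses decay more slowly than the recurrent ones, so the
# liquid's fading memory is dominated by the direct input echo (~one
# 50 ms window) rather than by self-sustained reverberation
TAU_SYN_REC = 8.0
TAU_SYN_SRC = 10.0
G_EXC = 0.002
G_INH = 4.0 * G_EXC
G_SRC_EXC = 0.005
G_SRC_INH = 0.005
# internal connection probabilities (exc/inh -> exc/inh)
P_EE, P_EI, P_IE, P_II = 0.1, 0.2, 0.25, 0.25


@dataclass
class LSMInfo:
    exc: np.ndarray
    inh: np.ndarray
    src_exc: np.ndarray
    src_inh: np.ndarray

    @property
    def liquid(self) -> np.ndarray:
        return np.concatenate([self.exc, self.inh])


def build_lsm(seed: int = 0) -> tuple[Network, LSMInfo]:
    rng = np.random.default_rng(seed)
    net = Network("lsm")
    exc = net.add_population("exc", N_EXC, LSM_PARAMS)
    inh = net.add_population("inh", N_INH, LSM_PARAMS)
    src_e = net.add_sources("src_exc", N_SRC)
    src_i = net.add_sources("src_inh", N_SRC)

    d_exc = net.add_internal_drivers("exc", +1, G_EXC, TAU_SYN_REC)
    d_inh = net.add_internal_drivers("inh", -1, G_INH, TAU_SYN_REC)
    d_se = net.add_source_drivers("src_exc", +1, G_SRC_EXC, TAU_SYN_SRC)
    d_si = net.add_source_drivers("src_inh", -1, G_SRC_INH, TAU_SYN_SRC)

    net.connect_drivers(d_exc, exc, p=P_EE, weight=1.0, rng=rng, allow_self=False)
    net.connect_drivers(d_exc, inh, p=P_EI, weight=1.0, rng=rng)
    net.connect_drivers(d_inh, exc, p=P_IE, weight=1.0, rng=rng)
    net.connect_drivers(d_inh, inh, p=P_II, weight=1.0, rng=rng, allow_self=False)

    # exactly 4 inputs per liquid neuron from each of the two source groups
    liquid = np.concatenate([exc, inh])
    for nid in liquid:
        for drivers in (d_se, d_si):
            picks = rng.choice(len(drivers), size=SRC_FAN_IN, replace=False)
            for k in picks:
                net.set_weight(int(drivers[k]), int(nid), 1.0)
    return net, LSMInfo(exc, inh, src_e, src_i)


def liquid_windows(spikes: SpikeData, liquid_ids: np.ndarray, t_ends,
                   window_ms: float = SEGMENT_MS):
    """Per-afferent spike lists (relative times) for each decision window.

    Returns a list over windows; each entry is a list of arrays, one per
    liquid neuron, containing that neuron's spike times relative to the
    window start.
    """
    pos = {int(u): k for k, u in enumerate(liquid_ids)}
    n_aff = len(liquid_ids)
    order = np.argsort(spikes.times, kind="stable")
    t_all = spikes.times[order]
    u_all = spikes.units[order]
    samples = []
    for t_end in t_ends:
        t0 = t_end - window_ms
        lo = np.searchsorted(t_all, t0, side="left")
        hi = np.searchsorted(t_all, t_end, side="left")
        per = [[] for _ in range(n_aff)]
        for t, u in zip(t_all[lo:hi], u_all[lo:hi]):
            k = pos.get(int(u))
            if k is not None:
                per[k].append(t - t0)
        samples.append([np.asarray(p) for p in per])
    return samples


def lsm_experiment(*, n_train: int = 1000, n_eval: int = 200, lag: int = 1,
                   jitter_sd: float = 1.0, seed: int = 0,
                   learning_rate: float = 2e-3, dt: float = 0.1,
                   template_seed: int = 42,
                   cfg: TempotronConfig | None = None) -> dict:
    """Full LSM classification run: stream, liquid, tempotron, evaluation.

    A continuous stream of ``n_train + n_eval + lag + 1`` 50 ms segments
    (each a jittered copy of template X or Y) is driven through the
    liquid once.  For every window the tempotron reads the liquid spikes
    of the 50 ms *decision* window that ends ``lag`` windows after the
    labeled segment, is trained on the first ``n_train`` windows and
    evaluated on the rest.  Returns accuracies and run metadata.
    """
    n_segments = n_train + n_eval + lag + 1
    T = n_segments * SEGMENT_MS
    net, info = build_lsm(seed=seed)
    templates = lsm_templates(2 * N_SRC, TEMPLATE_RATE,
                              TEMPLATE_SLICES * SEGMENT_MS, seed=template_seed)
    stream, labels = lsm_stream(templates, SEGMENT_MS, n_segments,
                                jitter_sd=jitter_sd, seed=seed + 1)
    out = simulate(net, stream, T, dt=dt, seed=seed + 2)
    liquid = info.liquid

    # decision window for segment j ends at (j + 1 + lag) * 50 ms
    usable = n_segments - lag - 1
    t_ends = [(j + 1 + lag) * SEGMENT_MS for j in range(usable)]
    samples = liquid_windows(out.spikes, liquid, t_ends)
    labels = labels[:usable]

    cfg = cfg or TempotronConfig(tau_m=15.0, tau_s=4.0, threshold=1.0,
                                 decision_window=(0.0, SEGMENT_MS),
                                 learning_rate=learning_rate,
                                 lr_decay_n0=250.0)
    n_train_eff = min(n_train, usable - 1)
    weights, errors = train(samples[:n_train_eff], labels[:n_train_eff], cfg,
                            n_afferents=liquid.size, seed=seed + 3)
    acc = evaluate(samples[n_train_eff:], labels[n_train_eff:], weights, cfg)
    return {
        "accuracy": acc,
        "train_errors": errors,
        "weights": weights,
        "mean_liquid_rate": len(out.spikes) / liquid.size / (T / 1000.0),
        "n_train": n_train_eff,
        "n_eval": usable - n_train_eff,
        "lag": lag,
        "seed": seed,
    }
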