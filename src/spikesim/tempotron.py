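"""Tempotron: a spike-based binary classifier with gradient-like learning.

The readout neuron sums PSP kernels from its afferents,

    V(t) = sum_j w_j sum_i K(t - t_ij),
    K(t) = A (exp(-t/tau_m) - exp(-t/tau_s)) Theta(t),

and reports class "+" by firing (V crosses threshold inside the decision
window) and class "-" by staying silent.  On an erroneous trial the weights
of all afferents with spikes before t_max (the tempotron's spike time, or
the time of the voltage maximum if it stayed silent) are nudged by
alpha * K(t_max - t_ij), downward after a false alarm and upward after a
miss.  This is gradient descent on the voltage at t_max.

Two variants: ``current`` (signed weights, analytic voltage) and
``conductance`` (per-afferent sign is fixed as on a hardware line driver,
weights are non-negative, excitatory updates are rescaled for the
asymmetric reversal-potential distances, and weights are requantized to
4 bits after each update).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .substrate import dequantize_weight, quantize_weight

__all__ = ["TempotronConfig", "kernel", "kernel_peak_time", "voltage_trace",
           "classify", "train_step", "train", "evaluate"]


@dataclass
class TempotronConfig:
    tau_m: float = 10.0  # ms
    tau_s: float = 2.5  # ms
    threshold: float = 1.0
    decision_window: tuple[float, float] = (0.0, 50.0)  # ms
    dt_eval: float = 0.2  # ms, voltage grid for the analytic variant
    learning_rate: float = 0.02
    lr_decay_n0: float | None = None  # alpha(n) = lr / (1 + n/n0); None = constant
    variant: str = "current"  # current | conductance
    # conductance-variant constants
    v_rest: float = -55.0
    E_exc: float = 0.0
    E_inh: float = -80.0
    weight_levels: int = 16
    weight_cap: float = 4.0  # |w| ceiling used for 4-bit requantization

    def __post_init__(self):
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("require tau_m > tau_s > 0")
        if self.variant not in ("current", "conductance"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def A(self) -> float:
        """Kernel scale normalizing the PSP peak to 1."""
        t_star = kernel_peak_time(self.tau_m, self.tau_s)
        return 1.0 / (math.exp(-t_star / self.tau_m) - math.exp(-t_star / self.tau_s))

    def alpha(self, n: int) -> float:
        if self.lr_decay_n0 is None:
            return self.learning_rate
        return self.learning_rate / (1.0 + n / self.lr_decay_n0)

    @property
    def exc_scale(self) -> float:
        """(V - E_inh) / (V - E_exc) magnitude ratio for conductance weights."""
        return abs((self.v_rest - self.E_inh) / (self.v_rest - self.E_exc))


def kernel_peak_time(tau_m: float, tau_s: float) -> float:
    return tau_m * tau_s / (tau_m - tau_s) * math.log(tau_m / tau_s)


def kernel(t_rel: np.ndarray | float, cfg: TempotronConfig) -> np.ndarray | float:
    """Peak-normalized PSP kernel; 0 for t_rel < 0."""
    t = np.asarray(t_rel, dtype=float)
    out = np.where(t >= 0,
                   cfg.A * (np.exp(-np.clip(t, 0, None) / cfg.tau_m)
                            - np.exp(-np.clip(t, 0, None) / cfg.tau_s)),
                   0.0)
    return out if np.ndim(t_rel) else float(out)


def _flatten(afferent_spikes) -> tuple[np.ndarray, np.ndarray]:
    ts, js = [], []
    for j, t in enumerate(afferent_spikes):
        t = np.asarray(t, dtype=float)
        ts.append(t)
        js.append(np.full(t.size, j, dtype=int))
    if not ts:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(ts), np.concatenate(js)


def voltage_trace(afferent_spikes, weights: np.ndarray, cfg: TempotronConfig
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic V(t) on the decision-window grid (current-based form)."""
    t0, t1 = cfg.decision_window
    grid = np.arange(t0, t1 + cfg.dt_eval / 2, cfg.dt_eval)
    t_sp, j_sp = _flatten(afferent_spikes)
    if t_sp.size == 0:
        return grid, np.zeros(grid.size)
    V = (weights[j_sp][:, None] * kernel(grid[None, :] - t_sp[:, None], cfg)).sum(axis=0)
    return grid, V


def classify(afferent_spikes, weights: np.ndarray, cfg: TempotronConfig
             ) -> tuple[bool, float]:
    """Decide spike/no-spike; return (spiked, t_max).

    In the current-based variant incoming spikes are blocked after the
    first output spike, so t_max is the first threshold crossing; for a
    silent trial t_max is the time of the voltage maximum (first such time
    for a flat trace).
    """
    grid, V = voltage_trace(afferent_spikes, _effective_weights(weights, cfg), cfg)
    above = np.nonzero(V >= cfg.threshold)[0]
    if above.size:
        return True, float(grid[above[0]])
    return False, float(grid[int(np.argmax(V))])


def _effective_weights(weights: np.ndarray, cfg: TempotronConfig) -> np.ndarray:
    if cfg.variant == "current":
        return weights
    # conductance form: efficacy of an excitatory line is reduced by the
    # smaller driving force toward E_exc relative to E_inh
    w = weights.copy()
    w[w > 0] /= cfg.exc_scale
    return w


def train_step(afferent_spikes, label: int, weights: np.ndarray,
               cfg: TempotronConfig, n: int = 0,
               signs: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """One learning iteration; returns (new weights, was_correct).

    label 1 means "should spike".  Correct trials leave the weights
    untouched; erroneous ones apply the +-alpha(n) sum_{t_ij < t_max}
    K(t_max - t_ij) update.  In the conductance variant excitatory updates
    are scaled by the reversal-potential ratio, sign crossings are clipped
    to zero, and weights are requantized to ``weight_levels``.
    """
    spiked, t_max = classify(afferent_spikes, weights, cfg)
    if spiked == bool(label):
        return weights, True
    direction = -1.0 if spiked else +1.0
    alpha = cfg.alpha(n)
    delta = np.zeros_like(weights)
    for j, t in enumerate(afferent_spikes):
        t = np.asarray(t, dtype=float)
        causal = t[t < t_max]
        if causal.size:
            delta[j] = float(np.sum(kernel(t_max - causal, cfg)))
    new = weights + direction * alpha * delta
    if cfg.variant == "conductance":
        if signs is None:
            signs = np.sign(weights)
        exc = signs > 0
        new = weights + direction * alpha * np.where(exc, delta * cfg.exc_scale, delta)
        # prohibit sign transitions: clip crossings to zero
        new = np.where(exc, np.clip(new, 0.0, cfg.weight_cap),
                       np.clip(new, -cfg.weight_cap, 0.0))
        lv = cfg.weight_levels
        q = np.array([quantize_weight(min(abs(w) / cfg.weight_cap, 1.0), lv) for w in new])
        new = np.sign(new) * np.array([dequantize_weight(int(i), lv) for i in q]) * cfg.weight_cap
    return new, False


def train(samples, labels, cfg: TempotronConfig, n_afferents: int,
          weights0: np.ndarray | None = None, seed: int = 0,
          signs: np.ndarray | None = None):
    """Train over (samples[i], labels[i]) pairs in order.

    ``samples`` is a sequence of afferent spike lists.  Returns the final
    weights and the per-iteration error indicator (1 = wrong).
    """
    rng = np.random.default_rng(seed)
    if weights0 is None:
        weights = 0.01 * rng.standard_normal(n_afferents)
        if cfg.variant == "conductance":
            if signs is None:
                signs = np.where(rng.random(n_afferents) < 0.8, 1.0, -1.0)
            weights = np.abs(weights) * signs
    else:
        weights = weights0.astype(float).copy()
    errors = np.zeros(len(samples), dtype=int)
    for n, (sample, label) in enumerate(zip(samples, labels)):
        weights, correct = train_step(sample, int(label), weights, cfg, n=n, signs=signs)
        errors[n] = 0 if correct else 1
    return weights, errors


def evaluate(samples, labels, weights: np.ndarray, cfg: TempotronConfig) -> float:
    """Fraction of samples classified correctly."""
    n_ok = 0
    for sample, label in zip(samples, labels):
        spiked, _ = classify(sample, weights, cfg)
        n_ok += int(spiked == bool(label))
    return n_ok / len(labels)
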