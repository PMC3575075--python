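"""Seeded stimulus generators for the benchmark networks.

Every generator is a pure function of its parameters and a seed and
returns a :class:`~spikesim.core.SpikeData` (plus side information where
the experiment needs it).  Unit ids are local (0..n-1); callers remap onto
network source ids with ``offset``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeData

__all__ = [
    "PulsePacket",
    "RatePattern",
    "pulse_packet",
    "poisson_sources",
    "gamma_process",
    "copula_rate_patterns",
    "lsm_templates",
    "lsm_stream",
]


@dataclass(frozen=True)
class PulsePacket:
    """A spike volley: ``a`` spikes per source, Gaussian spread ``sigma``."""

    a: int
    sigma: float  # ms
    t_center: float = 0.0  # ms
    n_sources: int = 100

    def __post_init__(self):
        if self.a < 0 or self.sigma < 0 or self.n_sources < 1:
            raise ValueError("require a >= 0, sigma >= 0, n_sources >= 1")


@dataclass(frozen=True)
class RatePattern:
    """One firing-rate vector (Hz per channel) held for ``duration`` ms."""

    rates: np.ndarray
    duration: float = 1000.0


def pulse_packet(pp: PulsePacket, seed: int = 0, offset: int = 0) -> SpikeData:
    """Draw ``a`` Gaussian(t_center, sigma) spike times per source.

    Early samples (t < t_center) are kept; clipping them would bias the
    realized spread.  The realized packet sigma is, by convention, the
    standard deviation of all emitted spike times.
    """
    rng = np.random.default_rng(seed)
    if pp.a == 0:
        return SpikeData.empty()
    times = rng.normal(pp.t_center, pp.sigma, size=(pp.n_sources, pp.a))
    units = np.repeat(np.arange(pp.n_sources) + offset, pp.a)
    return SpikeData(times.ravel(), units)


def poisson_sources(n: int, rate: float, T: float, seed: int = 0,
                    offset: int = 0) -> SpikeData:
    """Independent homogeneous Poisson spike trains at ``rate`` Hz for T ms."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    if rate == 0.0 or n == 0:
        return SpikeData.empty()
    counts = rng.poisson(rate * T / 1000.0, size=n)
    times = np.concatenate([np.sort(rng.uniform(0.0, T, size=c)) for c in counts])
    units = np.repeat(np.arange(n) + offset, counts)
    return SpikeData(times, units)


def gamma_process(rate: float, gamma_order: int, T: float, seed: int = 0,
                  n: int = 1, offset: int = 0) -> SpikeData:
    """Renewal spike trains with Gamma(shape=gamma_order) interspike intervals.

    Mean ISI is 1/rate, so the ISI CV is 1/sqrt(gamma_order); order 1 is
    the Poisson process.  The first interval is drawn like all others
    (ordinary renewal process).
    """
    if gamma_order < 1:
        raise ValueError("gamma_order must be >= 1")
    rng = np.random.default_rng(seed)
    if rate <= 0.0:
        return SpikeData.empty()
    mean_isi = 1000.0 / rate
    all_t, all_u = [], []
    for i in range(n):
        # draw enough ISIs to cover T with margin, extend if short
        est = max(8, int(1.5 * T / mean_isi) + 8)
        isi = rng.gamma(gamma_order, mean_isi / gamma_order, size=est)
        t = np.cumsum(isi)
        while t[-1] < T:
            isi = rng.gamma(gamma_order, mean_isi / gamma_order, size=est)
            t = np.concatenate([t, t[-1] + np.cumsum(isi)])
        t = t[t < T]
        all_t.append(t)
        all_u.append(np.full(t.size, i + offset, dtype=np.int64))
    if not all_t:
        return SpikeData.empty()
    return SpikeData(np.concatenate(all_t), np.concatenate(all_u))


def copula_rate_patterns(n_patterns: int, n_channels: int, target_corr: float,
                         r_min: float = 20.0, r_max: float = 55.0,
                         seed: int = 0) -> tuple[np.ndarray, float]:
    """Correlated rate vectors via a Gaussian copula with exponential marginals.

    A multivariate normal with uniform off-diagonal correlation
    ``target_corr`` is mapped through its CDF to uniforms, then through the
    unit-rate exponential quantile.  Values above e are clipped, divided by
    e onto [0, 1], and mapped affinely to [r_min, r_max].

    Returns the (n_patterns, n_channels) rate matrix and the empirical mean
    off-diagonal Pearson correlation of the channels.
    """
    if not 0.0 <= target_corr < 1.0:
        raise ValueError("target_corr must lie in [0, 1)")
    cov = np.full((n_channels, n_channels), target_corr)
    np.fill_diagonal(cov, 1.0)
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("target correlation matrix is not positive definite")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(n_channels), cov, size=n_patterns,
                                method="cholesky")
    u = stats.norm.cdf(z)
    x = -np.log1p(-u)          # unit-rate exponential quantile
    v = np.clip(x, None, np.e) / np.e
    rates = r_min + v * (r_max - r_min)
    c = np.corrcoef(rates, rowvar=False)
    off = c[~np.eye(n_channels, dtype=bool)]
    return rates, float(off.mean())


def rate_pattern_spikes(rates: np.ndarray, duration: float, gamma_order: int = 5,
                        n_per_channel: int = 1, seed: int = 0,
                        offset: int = 0) -> SpikeData:
    """Convert one rate vector into gamma-process spike trains.

    Channel i drives ``n_per_channel`` consecutive source units, all firing
    at rates[i]; used to present one odor-like pattern to the network.
    """
    parts = []
    rng = np.random.default_rng(seed)
    for i, r in enumerate(np.asarray(rates, dtype=float)):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        parts.append(gamma_process(r, gamma_order, duration, seed=sub,
                                   n=n_per_channel,
                                   offset=offset + i * n_per_channel))
    return SpikeData.merge(parts)


def lsm_templates(n_channels: int, rate: float, duration: float,
                  seed: int = 0) -> tuple[SpikeData, SpikeData]:
    """Two frozen Poisson template spike trains with identical rates."""
    x = poisson_sources(n_channels, rate, duration, seed=seed)
    y = poisson_sources(n_channels, rate, duration, seed=seed + 1)
    return x, y


def lsm_stream(templates: tuple[SpikeData, SpikeData], segment_ms: float,
               n_segments: int, jitter_sd: float = 1.0,
               seed: int = 0) -> tuple[SpikeData, np.ndarray]:
    """Segmented two-template stream with per-spike Gaussian timing jitter.

    For each 50 ms (by default) window a segment is drawn from template X
    or Y (fair coin); spikes are copied at their in-segment offsets, jitter
    with sd ``jitter_sd`` is added, and jittered spikes are folded back
    into their window by clipping so windows stay self-contained.  When a
    template is longer than one segment, window k uses template slice
    k mod n_template_segments.  Returns the stream and the 0/1 label per
    window (1 = template Y).
    """
    x, y = templates
    t_len = max(x.times.max(initial=0.0), y.times.max(initial=0.0))
    n_slices = max(1, int(t_len // segment_ms) or 1)
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n_segments)
    parts = []
    eps = 1e-6
    for k, lab in enumerate(labels):
        src = y if lab else x
        s = k % n_slices
        seg = src.window(s * segment_ms, (s + 1) * segment_ms)
        t = seg.times - s * segment_ms
        if jitter_sd > 0 and t.size:
            t = t + rng.normal(0.0, jitter_sd, size=t.size)
            t = np.clip(t, 0.0, segment_ms - eps)
        parts.append(SpikeData(t + k * segment_ms, seg.units))
    return SpikeData.merge(parts), labels
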