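"""Spike-train statistics used to characterize the benchmark networks.

Conventions: all standard deviations are population (1/N) standard
deviations; rates are in Hz, times in ms.  Each summary returns both the
aggregate and the per-unit values so callers can build reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpikeData

__all__ = [
    "PacketMeasurement",
    "MetricReport",
    "cv_isi",
    "cc_pairs",
    "measure_packets",
    "channel_correlation",
    "ring_rates",
    "attractor_stats",
]


@dataclass
class MetricReport:
    """Named results plus the metadata needed to regenerate them."""

    values: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]


# ---------------------------------------------------------------------------


def _psd(x: np.ndarray) -> float:
    """Population standard deviation (ddof=0)."""
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def cv_isi(spikes: SpikeData, unit_ids, min_spikes: int = 3):
    """Per-neuron coefficient of variation of interspike intervals.

    CV = sd(ISI) / mean(ISI); values near one indicate Poisson-like
    irregular firing.  Neurons with fewer than ``min_spikes`` spikes are
    excluded and reported.  Returns (mean CV, sd over neurons, per-neuron
    dict, excluded ids).
    """
    trains = spikes.spike_trains(unit_ids)
    per_neuron: dict[int, float] = {}
    excluded: list[int] = []
    for uid, t in trains.items():
        if t.size < min_spikes:
            excluded.append(uid)
            continue
        isi = np.diff(t)
        per_neuron[uid] = _psd(isi) / isi.mean()
    if not per_neuron:
        return float("nan"), float("nan"), per_neuron, excluded
    vals = np.array(list(per_neuron.values()))
    return float(vals.mean()), _psd(vals), per_neuron, excluded


def binned_counts(spikes: SpikeData, unit_ids, T: float, bin_ms: float = 2.0,
                  t0: float = 0.0) -> np.ndarray:
    """(n_units, n_bins) spike-count matrix over [t0, t0+T)."""
    ids = np.asarray(list(unit_ids), dtype=np.int64)
    n_bins = int(np.floor(T / bin_ms))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    counts = np.zeros((ids.size, n_bins))
    pos = {int(u): k for k, u in enumerate(ids)}
    mask = (spikes.times >= t0) & (spikes.times < t0 + n_bins * bin_ms)
    b = np.floor((spikes.times[mask] - t0) / bin_ms).astype(int)
    for u, bi in zip(spikes.units[mask], b):
        k = pos.get(int(u))
        if k is not None:
            counts[k, bi] += 1
    return counts


def cc_pairs(spikes: SpikeData, unit_ids, T: float, n_pairs: int = 1000,
             bin_ms: float = 2.0, seed: int = 0):
    """Pairwise spike-count correlation over randomly drawn distinct pairs.

    Counts are binned at ``bin_ms``; the Pearson correlation is computed
    per pair; pairs containing a zero-variance train are redrawn (and
    counted).  Returns (mean CC, sd over pairs, per-pair array, n_redrawn).
    """
    ids = np.asarray(list(unit_ids), dtype=np.int64)
    if ids.size < 2:
        raise ValueError("need at least 2 units")
    counts = binned_counts(spikes, ids, T, bin_ms)
    var = counts.var(axis=1)
    rng = np.random.default_rng(seed)
    cc = np.empty(n_pairs)
    n_redrawn = 0
    centered = counts - counts.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=1))
    k = 0
    guard = 0
    while k < n_pairs:
        i, j = rng.integers(0, ids.size, size=2)
        if i == j:
            continue
        if var[i] == 0.0 or var[j] == 0.0:
            n_redrawn += 1
            guard += 1
            if guard > 100 * n_pairs:
                raise RuntimeError("too many zero-variance trains for CC estimate")
            continue
        cc[k] = float(centered[i] @ centered[j] / (norm[i] * norm[j]))
        k += 1
    return float(cc.mean()), _psd(cc), cc, n_redrawn


@dataclass(frozen=True)
class PacketMeasurement:
    """One pulse-packet traversal: mean spikes/neuron and temporal spread."""

    a: float
    sigma: float  # ms
    group_index: int
    window: tuple[float, float]
    n_spikes: int


def measure_packets(spikes: SpikeData, group_ids, group_index: int = 0,
                    gap_ms: float = 5.0, group_size: int | None = None):
    """Split a group's spikes into traversals at gaps > ``gap_ms`` and
    measure (a, sigma) per traversal.

    a = spike count / group size; sigma = population sd of the spike times
    in the window (0 for a silent or single-spike traversal).
    """
    ids = np.asarray(list(group_ids), dtype=np.int64)
    size = group_size or ids.size
    sub = spikes.select(ids)
    if len(sub) == 0:
        return [PacketMeasurement(0.0, 0.0, group_index, (0.0, 0.0), 0)]
    t = np.sort(sub.times)
    splits = np.nonzero(np.diff(t) > gap_ms)[0] + 1
    out = []
    for chunk in np.split(t, splits):
        sigma = _psd(chunk) if chunk.size > 1 else 0.0
        out.append(PacketMeasurement(chunk.size / size, sigma, group_index,
                                     (float(chunk[0]), float(chunk[-1])), chunk.size))
    return out


def channel_correlation(rates_by_presentation: np.ndarray):
    """Channel-correlation matrix of rate vectors across presentations.

    ``rates_by_presentation`` is (n_presentations, n_channels), one rate
    per channel per stimulus (for a glomerulus: the mean over its units).
    Returns the Pearson matrix and the (median, 20th, 80th percentile) of
    its off-diagonal entries.
    """
    r = np.asarray(rates_by_presentation, dtype=float)
    if r.shape[0] < 2:
        raise ValueError("need at least 2 presentations")
    C = np.corrcoef(r, rowvar=False)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    summary = (float(np.median(off)), float(np.percentile(off, 20)),
               float(np.percentile(off, 80)))
    return C, summary


def ring_rates(spikes: SpikeData, half_a, half_b, T: float, t0: float = 0.0):
    """Mean per-neuron firing rate (Hz) of the two half-rings."""
    out = []
    for ids in (half_a, half_b):
        ids = np.asarray(list(ids), dtype=np.int64)
        mask = (spikes.times >= t0) & (spikes.times < t0 + T) & np.isin(spikes.units, ids)
        out.append(float(mask.sum() / ids.size / (T / 1000.0)))
    return tuple(out)


def rate_profile(spikes: SpikeData, unit_ids, T: float, t0: float = 0.0) -> np.ndarray:
    ids = np.asarray(list(unit_ids), dtype=np.int64)
    mask = (spikes.times >= t0) & (spikes.times < t0 + T)
    u = spikes.units[mask]
    return np.array([(u == i).sum() for i in ids]) / (T / 1000.0)


# ---------------------------------------------------------------------------
# attractor statistics


def _smoothed_pattern_rates(spikes: SpikeData, patterns, T: float, bin_ms: float,
                            smooth_ms: float) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(np.floor(T / bin_ms))
    rates = np.zeros((len(patterns), n_bins))
    for k, ids in enumerate(patterns):
        ids = np.asarray(list(ids), dtype=np.int64)
        mask = np.isin(spikes.units, ids) & (spikes.times < n_bins * bin_ms)
        b = np.floor(spikes.times[mask] / bin_ms).astype(int)
        np.add.at(rates[k], b, 1.0)
        rates[k] /= ids.size * bin_ms / 1000.0
    w = max(1, int(round(smooth_ms / bin_ms)))
    kernel = np.ones(w) / w
    smoothed = np.vstack([np.convolve(r, kernel, mode="same") for r in rates])
    return smoothed, np.arange(n_bins) * bin_ms + bin_ms / 2


def attractor_stats(spikes: SpikeData, patterns, T: float, *,
                    bin_ms: float = 5.0, smooth_ms: float = 20.0,
                    active_frac: float = 0.5,
                    traces: dict[int, np.ndarray] | None = None,
                    trace_times: np.ndarray | None = None,
                    pattern_of_neuron: dict[int, int] | None = None):
    """Dwell times, UP-state voltages, and dominance from pattern activity.

    A pattern is *active* while its smoothed (boxcar ``smooth_ms``)
    pyramidal rate exceeds ``active_frac`` of the run's peak pattern rate.
    Returns a MetricReport with per-pattern dwell intervals (ms), dwell
    time statistics, per-pattern active-time fractions, and, when traces
    are supplied, mean membrane potential inside vs outside the owning
    pattern's active epochs.
    """
    smoothed, centers = _smoothed_pattern_rates(spikes, patterns, T, bin_ms, smooth_ms)
    peak = smoothed.max() if smoothed.size else 0.0
    thr = active_frac * peak
    dwell_intervals: list[list[tuple[float, float]]] = []
    dwell_times: list[float] = []
    active_frac_per_pattern = []
    active_masks = []
    for k in range(len(patterns)):
        act = smoothed[k] > thr
        active_masks.append(act)
        intervals = []
        in_run = False
        for i, a in enumerate(act):
            if a and not in_run:
                start = i
                in_run = True
            elif not a and in_run:
                intervals.append((centers[start] - bin_ms / 2, centers[i - 1] + bin_ms / 2))
                in_run = False
        if in_run:
            intervals.append((centers[start] - bin_ms / 2, centers[-1] + bin_ms / 2))
        dwell_intervals.append(intervals)
        dwell_times.extend(b - a for a, b in intervals)
        active_frac_per_pattern.append(float(act.mean()))

    rep = MetricReport()
    rep.values["dwell_intervals"] = dwell_intervals
    rep.values["dwell_times"] = np.asarray(dwell_times)
    rep.values["mean_dwell"] = float(np.mean(dwell_times)) if dwell_times else 0.0
    rep.values["active_fraction"] = np.asarray(active_frac_per_pattern)
    rep.values["dominant_pattern"] = int(np.argmax(active_frac_per_pattern))
    rep.values["smoothed_rates"] = smoothed
    rep.values["rate_bin_centers"] = centers

    if traces and trace_times is not None and pattern_of_neuron:
        v_in, v_out = [], []
        for nid, v in traces.items():
            k = pattern_of_neuron.get(int(nid))
            if k is None:
                continue
            act = np.zeros(trace_times.size, dtype=bool)
            for a, b in dwell_intervals[k]:
                act |= (trace_times >= a) & (trace_times < b)
            if act.any():
                v_in.append(v[act].mean())
            if (~act).any():
                v_out.append(v[~act].mean())
        rep.values["up_state_vm"] = float(np.mean(v_in)) if v_in else float("nan")
        rep.values["down_state_vm"] = float(np.mean(v_out)) if v_out else float("nan")
    return rep
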