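"""Clock-driven simulation of conductance-based LIF networks.

The neuron model is the standard leaky integrate-and-fire equation with
conductance-based synapses,

    C_m dV/dt = -g_l (V - E_l) - sum_i g_i(t) (V - E_i),

where each synaptic conductance decays exponentially after a presynaptic
spike.  Synaptic input is organized the way accelerated mixed-signal
neuromorphic chips organize it: each presynaptic unit (an on-chip neuron or
an external spike source) owns one *line driver* that carries the sign, the
peak conductance ``g_max``, the decay time constant ``tau_fall`` and an
optional short-term-plasticity setting for that axon; the per-synapse weight
``w`` in [0, 1] scales ``g_max`` individually for every target neuron
(``g = w * g_max * p(t)``).

Integration uses exponential Euler with conductances held constant over one
step, which is exact for the leak term and stable in high-conductance
regimes.  Threshold crossings are detected at step end; the spike timestamp
is the step-end time.  All quantities are in the biological domain:
ms, mV, nF, uS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "STPParams",
    "SpikeData",
    "Network",
    "SimResult",
    "step_membrane",
    "conductance_course",
    "stp_efficacy",
    "simulate",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron parameters (biological units).

    Defaults give tau_m = C_m / g_l = 10 ms with a 15 mV threshold distance.
    """

    C_m: float = 0.2  # nF
    g_l: float = 0.02  # uS
    E_l: float = -70.0  # mV
    E_exc: float = 0.0  # mV
    E_inh: float = -80.0  # mV
    V_th: float = -55.0  # mV
    V_reset: float = -70.0  # mV
    tau_refrac: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_l <= 0:
            raise ValueError("C_m and g_l must be positive")
        if self.V_reset > self.V_th:
            raise ValueError("V_reset must not exceed V_th")
        if self.E_inh >= self.E_exc:
            raise ValueError("E_inh must lie below E_exc")
        if self.tau_refrac < 0:
            raise ValueError("tau_refrac must be non-negative")

    @property
    def tau_m(self) -> float:
        return self.C_m / self.g_l


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity of a line driver (Tsodyks-Markram style).

    ``depressing`` releases a fraction U_SE of a resource pool that recovers
    with tau_rec; ``facilitating`` accumulates utilization with tau_facil.
    The efficacy of the first spike after a long pause is U_SE in both modes.
    """

    mode: str = "off"  # off | depressing | facilitating
    U_SE: float = 0.4
    tau_rec: float = 150.0  # ms
    tau_facil: float = 150.0  # ms

    def __post_init__(self) -> None:
        if self.mode not in ("off", "depressing", "facilitating"):
            raise ValueError(f"unknown STP mode {self.mode!r}")
        if not 0.0 <= self.U_SE <= 1.0:
            raise ValueError("U_SE must lie in [0, 1]")
        if self.tau_rec <= 0 or self.tau_facil <= 0:
            raise ValueError("STP time constants must be positive")


# ---------------------------------------------------------------------------
# spike container


class SpikeData:
    """Ordered spike events ``(time_ms, unit_id)``.

    The universal exchange object between stimulus generators, the
    simulator, and the metrics: a pair of aligned arrays sorted by time.
    """

    __slots__ = ("times", "units")

    def __init__(self, times: Iterable[float], units: Iterable[int], *, sort: bool = True):
        t = np.asarray(times, dtype=float)
        u = np.asarray(units, dtype=np.int64)
        if t.shape != u.shape:
            raise ValueError("times and units must have equal length")
        if sort and t.size and np.any(np.diff(t) < 0):
            order = np.argsort(t, kind="stable")
            t, u = t[order], u[order]
        self.times = t
        self.units = u

    @classmethod
    def empty(cls) -> "SpikeData":
        return cls(np.empty(0), np.empty(0, dtype=np.int64), sort=False)

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeData):
            return NotImplemented
        return np.array_equal(self.times, other.times) and np.array_equal(self.units, other.units)

    def select(self, unit_ids: Iterable[int]) -> "SpikeData":
        mask = np.isin(self.units, np.asarray(list(unit_ids), dtype=np.int64))
        return SpikeData(self.times[mask], self.units[mask], sort=False)

    def window(self, t0: float, t1: float) -> "SpikeData":
        mask = (self.times >= t0) & (self.times < t1)
        return SpikeData(self.times[mask], self.units[mask], sort=False)

    def shift(self, dt: float) -> "SpikeData":
        return SpikeData(self.times + dt, self.units, sort=False)

    @staticmethod
    def merge(parts: Sequence["SpikeData"]) -> "SpikeData":
        if not parts:
            return SpikeData.empty()
        t = np.concatenate([p.times for p in parts])
        u = np.concatenate([p.units for p in parts])
        return SpikeData(t, u)

    def spike_trains(self, unit_ids: Iterable[int]) -> dict[int, np.ndarray]:
        """Per-unit sorted spike-time arrays (empty array for silent units)."""
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.units, kind="stable")
        units_sorted = self.units[order]
        times_sorted = self.times[order]
        for uid in list(unit_ids):
            lo = np.searchsorted(units_sorted, uid, side="left")
            hi = np.searchsorted(units_sorted, uid, side="right")
            out[uid] = np.sort(times_sorted[lo:hi])
        return out


# ---------------------------------------------------------------------------
# network container


_NO_STP = STPParams()


class Network:
    """A network under construction: populations, drivers, weight matrix.

    Neurons are numbered globally; external sources live in a separate
    global id space.  One driver per presynaptic axon; the weight matrix is
    (n_drivers, n_neurons) with entries in [0, 1].
    """

    def __init__(self, name: str = "net"):
        self.name = name
        self.populations: dict[str, np.ndarray] = {}
        self.source_groups: dict[str, np.ndarray] = {}
        self._params: list[NeuronParams] = []
        # driver columns
        self.driver_sign: list[int] = []
        self.driver_source_kind: list[str] = []  # "int" | "ext"
        self.driver_source_id: list[int] = []
        self.driver_g_max: list[float] = []
        self.driver_tau_fall: list[float] = []
        self.driver_stp: list[STPParams] = []
        self._weights: dict[tuple[int, int], float] = {}
        self._neuron_drivers: dict[int, list[int]] = {}
        self._source_drivers: dict[int, list[int]] = {}
        self.delay_ms: float = 1.0
        self.membrane_noise_sd: float = 0.0  # mV / sqrt(ms)

    # -- construction -------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self._params)

    @property
    def n_sources(self) -> int:
        return sum(len(v) for v in self.source_groups.values())

    @property
    def n_drivers(self) -> int:
        return len(self.driver_sign)

    def add_population(self, name: str, n: int, params: NeuronParams) -> np.ndarray:
        if name in self.populations:
            raise ValueError(f"population {name!r} already exists")
        ids = np.arange(self.n_neurons, self.n_neurons + n)
        self._params.extend([params] * n)
        self.populations[name] = ids
        return ids

    def add_sources(self, name: str, n: int) -> np.ndarray:
        if name in self.source_groups:
            raise ValueError(f"source group {name!r} already exists")
        start = self.n_sources
        ids = np.arange(start, start + n)
        self.source_groups[name] = ids
        return ids

    def _add_driver(self, kind: str, source_id: int, sign: int, g_max: float,
                    tau_fall: float, stp: STPParams) -> int:
        if g_max < 0:
            raise ValueError("g_max must be non-negative")
        if tau_fall <= 0:
            raise ValueError("tau_fall must be positive")
        d = self.n_drivers
        self.driver_sign.append(sign)
        self.driver_source_kind.append(kind)
        self.driver_source_id.append(source_id)
        self.driver_g_max.append(g_max)
        self.driver_tau_fall.append(tau_fall)
        self.driver_stp.append(stp)
        table = self._neuron_drivers if kind == "int" else self._source_drivers
        table.setdefault(source_id, []).append(d)
        return d

    def add_internal_drivers(self, pop: str, sign: int, g_max: float, tau_fall: float,
                             stp: STPParams = _NO_STP) -> np.ndarray:
        """One line driver per neuron of ``pop`` (its axon)."""
        return np.array([
            self._add_driver("int", int(nid), sign, g_max, tau_fall, stp)
            for nid in self.populations[pop]
        ])

    def add_source_drivers(self, group: str, sign: int, g_max: float, tau_fall: float,
                           stp: STPParams = _NO_STP) -> np.ndarray:
        return np.array([
            self._add_driver("ext", int(sid), sign, g_max, tau_fall, stp)
            for sid in self.source_groups[group]
        ])

    def drivers_of_neuron(self, nid: int) -> list[int]:
        return self._neuron_drivers.get(int(nid), [])

    def drivers_of_source(self, sid: int) -> list[int]:
        return self._source_drivers.get(int(sid), [])

    def set_weight(self, driver: int, neuron: int, w: float) -> None:
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w} outside [0, 1]")
        if w == 0.0:
            self._weights.pop((driver, neuron), None)
        else:
            self._weights[(int(driver), int(neuron))] = float(w)

    def get_weight(self, driver: int, neuron: int) -> float:
        return self._weights.get((int(driver), int(neuron)), 0.0)

    def connect_drivers(self, drivers: Sequence[int], post_ids: Sequence[int], *,
                        p: float | None = None, in_degree: int | None = None,
                        weight: float | Callable[[int, int], float] = 1.0,
                        rng: np.random.Generator | None = None,
                        allow_self: bool = True) -> int:
        """Wire ``drivers`` onto ``post_ids`` by Bernoulli(p) or fixed in-degree.

        ``weight`` may be a constant or a function of (driver_position,
        post_position) returning a weight in [0, 1].  Returns the number of
        synapses created.  ``allow_self=False`` skips driver k -> neuron whose
        id equals the driver's source id (no autapses).
        """
        if (p is None) == (in_degree is None):
            raise ValueError("exactly one of p / in_degree must be given")
        rng = rng or np.random.default_rng()
        n_syn = 0
        drivers = list(drivers)
        for j, post in enumerate(post_ids):
            if in_degree is not None:
                candidates = [k for k, d in enumerate(drivers)
                              if allow_self or not (self.driver_source_kind[d] == "int"
                                                    and self.driver_source_id[d] == post)]
                if in_degree > len(candidates):
                    raise ValueError("in_degree exceeds number of candidate drivers")
                chosen = rng.choice(len(candidates), size=in_degree, replace=False)
                picks = [candidates[int(c)] for c in chosen]
            else:
                mask = rng.random(len(drivers)) < p
                picks = [k for k in np.nonzero(mask)[0]
                         if allow_self or not (self.driver_source_kind[drivers[k]] == "int"
                                               and self.driver_source_id[drivers[k]] == post)]
            for k in picks:
                w = weight(k, j) if callable(weight) else weight
                if w > 0:
                    self.set_weight(drivers[k], int(post), min(float(w), 1.0))
                    n_syn += 1
        return n_syn

    # -- compiled views -----------------------------------------------------

    def param_arrays(self) -> dict[str, np.ndarray]:
        fields = ("C_m", "g_l", "E_l", "E_exc", "E_inh", "V_th", "V_reset", "tau_refrac")
        return {f: np.array([getattr(p, f) for p in self._params]) for f in fields}

    def set_neuron_param(self, nid: int, **kwargs) -> None:
        self._params[int(nid)] = replace(self._params[int(nid)], **kwargs)

    def neuron_param(self, nid: int) -> NeuronParams:
        return self._params[int(nid)]

    def weight_matrix(self) -> np.ndarray:
        W = np.zeros((self.n_drivers, self.n_neurons))
        for (d, n), w in self._weights.items():
            W[d, n] = w
        return W

    def fan_in(self) -> np.ndarray:
        """Number of non-zero afferent synapses per neuron."""
        counts = np.zeros(self.n_neurons, dtype=int)
        for (_, n) in self._weights:
            counts[n] += 1
        return counts

    def population_of(self, nid: int) -> str:
        for name, ids in self.populations.items():
            if nid in ids:
                return name
        raise KeyError(nid)


# ---------------------------------------------------------------------------
# elementary operations (exposed for direct use and for testing)


def step_membrane(V: np.ndarray, g_exc: np.ndarray, g_inh: np.ndarray, dt: float,
                  C_m: np.ndarray, g_l: np.ndarray, E_l: np.ndarray,
                  E_exc: np.ndarray, E_inh: np.ndarray) -> np.ndarray:
    """Advance the membrane by one exponential-Euler step.

    Conductances are held constant over the step, so the update relaxes V
    toward the instantaneous equilibrium potential with the instantaneous
    effective time constant C_m / g_tot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_tot = g_l + g_exc + g_inh
    V_inf = (g_l * E_l + g_exc * E_exc + g_inh * E_inh) / g_tot
    return V_inf + (V - V_inf) * np.exp(-(g_tot * dt) / C_m)


def stp_efficacy(stp: STPParams, spike_times: np.ndarray) -> np.ndarray:
    """Per-spike efficacy factors for a driver's sorted spike train.

    depressing:  eta_k = R_k * U_SE,
                 R_{k+1} = 1 - (1 - R_k (1 - U_SE)) exp(-dt/tau_rec), R_1 = 1
    facilitating: eta_k = u_k,  u jumps by U_SE (1 - u) at each spike and
                 decays to zero with tau_facil between spikes.
    Both give first-spike efficacy U_SE; mode 'off' gives all ones.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted")
    if stp.mode == "off":
        return np.ones(t.size)
    eff = np.empty(t.size)
    if stp.mode == "depressing":
        R = 1.0
        for k in range(t.size):
            eff[k] = R * stp.U_SE
            if k + 1 < t.size:
                dt_k = t[k + 1] - t[k]
                R = 1.0 - (1.0 - R * (1.0 - stp.U_SE)) * math.exp(-dt_k / stp.tau_rec)
    else:  # facilitating
        u = 0.0
        for k in range(t.size):
            u = u + stp.U_SE * (1.0 - u)
            eff[k] = u
            if k + 1 < t.size:
                u *= math.exp(-(t[k + 1] - t[k]) / stp.tau_facil)
    return eff


def conductance_course(w: float, g_max: float, tau_fall: float,
                       spike_times: np.ndarray, t: np.ndarray | float,
                       stp: STPParams = _NO_STP) -> np.ndarray | float:
    """Analytic synaptic conductance g(t) = w g_max sum_k eta_k e^{-(t-t_k)/tau}.

    The rising edge is treated as instantaneous.  Used as the closed-form
    reference for the clock-driven engine.
    """
    st = np.asarray(spike_times, dtype=float)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    eff = stp_efficacy(stp, st)
    g = np.zeros_like(tt)
    for t_k, eta in zip(st, eff):
        mask = tt >= t_k
        g[mask] += eta * np.exp(-(tt[mask] - t_k) / tau_fall)
    g *= w * g_max
    return g if np.ndim(t) else float(g[0])


# ---------------------------------------------------------------------------
# the simulation loop


@dataclass
class SimResult:
    spikes: SpikeData
    trace_times: np.ndarray | None = None
    traces: dict[int, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def rates(self, unit_ids: Iterable[int], T: float, t0: float = 0.0) -> np.ndarray:
        """Mean firing rate in Hz per unit over [t0, t0+T] (T in ms)."""
        ids = np.asarray(list(unit_ids), dtype=np.int64)
        mask = (self.spikes.times >= t0) & (self.spikes.times < t0 + T)
        counts = np.array([(self.spikes.units[mask] == uid).sum() for uid in ids])
        return counts / (T / 1000.0)


class _OnlineSTP:
    """Per-driver TM state advanced at presynaptic spike arrivals."""

    def __init__(self, stps: Sequence[STPParams]):
        self.stps = stps
        self.R = np.ones(len(stps))
        self.u = np.zeros(len(stps))
        self.last_t = np.full(len(stps), -np.inf)

    def efficacy(self, d: int, t: float) -> float:
        stp = self.stps[d]
        if stp.mode == "off":
            return 1.0
        dt = t - self.last_t[d]
        if stp.mode == "depressing":
            if np.isfinite(dt):
                self.R[d] = 1.0 - (1.0 - self.R[d] * (1.0 - stp.U_SE)) * math.exp(-dt / stp.tau_rec)
            eta = self.R[d] * stp.U_SE
            self.last_t[d] = t
            return eta
        # facilitating
        if np.isfinite(dt):
            self.u[d] *= math.exp(-dt / stp.tau_facil)
        self.u[d] = self.u[d] + stp.U_SE * (1.0 - self.u[d])
        self.last_t[d] = t
        return self.u[d]


def simulate(network: Network, stimuli: SpikeData | None, T: float, *,
             dt: float = 0.1, seed: int = 0,
             record_v: Sequence[int] = ()) -> SimResult:
    """Run the network for T ms and return all internal spikes.

    Internal spikes are fed back through the emitting neuron's line driver
    with the configured axonal delay; external stimulus spikes reach their
    drivers with the same delay.  Deterministic for fixed
    (network, stimuli, seed, dt).  Up to 8 membrane traces can be recorded.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    if len(record_v) > 8:
        raise ValueError("at most 8 membrane traces can be recorded")
    stimuli = stimuli if stimuli is not None else SpikeData.empty()

    n = network.n_neurons
    pa = network.param_arrays()
    C_m, g_l = pa["C_m"], pa["g_l"]
    E_l, E_exc, E_inh = pa["E_l"], pa["E_exc"], pa["E_inh"]
    V_th, V_reset, tau_refrac = pa["V_th"], pa["V_reset"], pa["tau_refrac"]

    nd = network.n_drivers
    sign = np.asarray(network.driver_sign)
    g_max = np.asarray(network.driver_g_max, dtype=float)
    tau_fall = np.asarray(network.driver_tau_fall, dtype=float)
    exc_idx = np.nonzero(sign > 0)[0]
    inh_idx = np.nonzero(sign < 0)[0]
    W = network.weight_matrix()
    M_exc = (W[exc_idx, :] * g_max[exc_idx, None]).T.copy() if exc_idx.size else None
    M_inh = (W[inh_idx, :] * g_max[inh_idx, None]).T.copy() if inh_idx.size else None

    n_steps = int(round(T / dt))
    delay_steps = max(1, int(round(network.delay_ms / dt)))

    # validate stimulus sources and precompute external driver events
    known_sources = set()
    for ids in network.source_groups.values():
        known_sources.update(int(i) for i in ids)
    if len(stimuli):
        bad = set(int(u) for u in np.unique(stimuli.units)) - known_sources
        if bad:
            raise ValueError(f"stimulus references unknown source ids {sorted(bad)[:5]}")

    ext_steps: list[int] = []
    ext_drv: list[int] = []
    ext_eff: list[float] = []
    if len(stimuli):
        for sid in np.unique(stimuli.units):
            drivers = network.drivers_of_source(int(sid))
            if not drivers:
                continue
            st = np.sort(stimuli.times[stimuli.units == sid])
            steps = np.floor(st / dt).astype(int) + delay_steps
            keep = (steps >= 0) & (steps < n_steps)
            for d in drivers:
                eff = stp_efficacy(network.driver_stp[d], st)
                ext_steps.extend(steps[keep])
                ext_drv.extend([d] * int(keep.sum()))
                ext_eff.extend(eff[keep])
    if ext_steps:
        order = np.argsort(np.asarray(ext_steps), kind="stable")
        ext_steps_a = np.asarray(ext_steps)[order]
        ext_drv_a = np.asarray(ext_drv)[order]
        ext_eff_a = np.asarray(ext_eff)[order]
    else:
        ext_steps_a = np.empty(0, dtype=int)
        ext_drv_a = np.empty(0, dtype=int)
        ext_eff_a = np.empty(0)

    decay = np.exp(-dt / tau_fall) if nd else np.empty(0)
    y = np.zeros(nd)
    ring = np.zeros((delay_steps, nd))
    online_stp = _OnlineSTP(network.driver_stp)

    rng = np.random.default_rng(seed)
    noise_sd = network.membrane_noise_sd
    V = E_l.copy()
    refrac_until = np.full(n, -np.inf)

    out_t: list[float] = []
    out_u: list[int] = []
    rec_ids = [int(i) for i in record_v]
    trace = np.empty((n_steps, len(rec_ids))) if rec_ids else None

    ptr = 0
    n_ext = ext_steps_a.size
    zeros = np.zeros(n)
    for step in range(n_steps):
        t_start = step * dt
        t_end = t_start + dt
        # synaptic state
        if nd:
            y *= decay
            while ptr < n_ext and ext_steps_a[ptr] == step:
                y[ext_drv_a[ptr]] += ext_eff_a[ptr]
                ptr += 1
            slot = ring[step % delay_steps]
            y += slot
            slot[:] = 0.0
            ge = M_exc @ y[exc_idx] if M_exc is not None else zeros
            gi = M_inh @ y[inh_idx] if M_inh is not None else zeros
        else:
            ge = gi = zeros
        # membrane update
        V = step_membrane(V, ge, gi, dt, C_m, g_l, E_l, E_exc, E_inh)
        if noise_sd > 0.0:
            V = V + noise_sd * math.sqrt(dt) * rng.standard_normal(n)
        refractory = t_start < refrac_until - 1e-12
        V[refractory] = V_reset[refractory]
        fired = (~refractory) & (V >= V_th)
        if fired.any():
            ids = np.nonzero(fired)[0]
            V[ids] = V_reset[ids]
            refrac_until[ids] = t_end + tau_refrac[ids]
            out_t.extend([t_end] * ids.size)
            out_u.extend(int(i) for i in ids)
            target_slot = (step + delay_steps) % delay_steps
            for nid in ids:
                for d in network.drivers_of_neuron(int(nid)):
                    ring[target_slot, d] += online_stp.efficacy(d, t_end)
        if trace is not None:
            trace[step, :] = V[rec_ids]
        if step % 2000 == 1999 and not np.all(np.isfinite(V)):
            bad = int(np.nonzero(~np.isfinite(V))[0][0])
            raise RuntimeError(f"non-finite membrane potential at neuron {bad}, t={t_end} ms")

    if not np.all(np.isfinite(V)):
        bad = int(np.nonzero(~np.isfinite(V))[0][0])
        raise RuntimeError(f"non-finite membrane potential at neuron {bad}, t={T} ms")

    spikes = SpikeData(np.asarray(out_t), np.asarray(out_u, dtype=np.int64), sort=True)
    result = SimResult(spikes=spikes, meta={"T": T, "dt": dt, "seed": seed,
                                            "n_neurons": n, "n_drivers": nd})
    if trace is not None:
        result.trace_times = (np.arange(n_steps) + 1) * dt
        result.traces = {nid: trace[:, k] for k, nid in enumerate(rec_ids)}
    return result
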