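"""Structural constraints and imperfections of the analog substrate.

An accelerated mixed-signal neural chip imposes limits a pure software
network does not have: a bounded number of neurons and synapse line
drivers, 4-bit synaptic weights, voltage parameters shared between blocks
of neurons, a fixed axonal delay, and analog imperfections.  The latter
come in two kinds: *fixed-pattern noise* (static unit-to-unit parameter
scatter from device mismatch, frozen per chip instance) and trial-to-trial
noise (thermal/electronic fluctuations of dynamic variables).

``apply_substrate`` turns an ideal network into its constrained, noisy
counterpart; with all noise amplitudes at zero it reduces to weight
quantization plus parameter sharing, so the substrate path can be checked
exactly against the ideal path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Network

__all__ = [
    "NoiseModel",
    "SubstrateConfig",
    "SubstrateViolation",
    "SubstrateReport",
    "quantize_weight",
    "dequantize_weight",
    "apply_fixed_pattern_noise",
    "enforce_shared_parameters",
    "apply_substrate",
]


@dataclass(frozen=True)
class NoiseModel:
    """Imperfection amplitudes of one chip instance.

    Fixed-pattern draws are frozen by ``chip_seed`` (one chip = one seed);
    trial-to-trial membrane noise is drawn from the run seed instead.
    Conductance scatter is lognormal (positive, median preserved up to
    ``fp_gl_median``); threshold scatter is Gaussian.  ``fp_gl_median`` is a
    systematic offset of the leak conductance: the uncalibrated membrane
    time constant sits at ``tau_target / fp_gl_median``.  The defaults
    (median factor 0.662, CV 0.48) emulate an uncalibrated chip whose
    tau_m distribution has median ~15.1 ms and 20th/80th percentiles
    ~10.3 / 22.1 ms for a 10 ms target.
    """

    fp_gl_cv: float = 0.48
    fp_gl_median: float = 0.662
    fp_gmax_cv: float = 0.2
    fp_vth_sd: float = 2.0  # mV
    membrane_noise_sd: float = 0.2  # mV / sqrt(ms)
    chip_seed: int = 0

    def __post_init__(self):
        for name in ("fp_gl_cv", "fp_gl_median", "fp_gmax_cv", "fp_vth_sd", "membrane_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @staticmethod
    def silent(chip_seed: int = 0) -> "NoiseModel":
        return NoiseModel(fp_gl_cv=0.0, fp_gl_median=1.0, fp_gmax_cv=0.0,
                          fp_vth_sd=0.0, membrane_noise_sd=0.0, chip_seed=chip_seed)


@dataclass(frozen=True)
class SubstrateConfig:
    """Chip-level resource limits and constants."""

    n_neurons_total: int = 384
    n_neurons_per_block: int = 192
    n_drivers: int = 256
    max_internal_sources: int = 192
    weight_levels: int = 16
    shared_voltage_group_size: int = 96
    axonal_delay: float = 1.0  # ms
    noise: NoiseModel = field(default_factory=NoiseModel)


class SubstrateViolation(ValueError):
    """The network cannot be mapped onto the substrate."""


@dataclass
class SubstrateReport:
    coercions: list[tuple[int, str, float, float]] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"substrate report: {len(self.coercions)} coercions, "
                 f"{len(self.violations)} violations"]
        lines += [f"  VIOLATION: {v}" for v in self.violations]
        lines += [f"  coerced neuron {n}: {f} {old:.3f} -> {new:.3f}"
                  for n, f, old, new in self.coercions]
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def quantize_weight(w: float, levels: int = 16) -> int:
    """Nearest of ``levels`` equidistant values in [0, 1]; ties round up."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight {w} outside [0, 1]")
    return int(np.floor(w * (levels - 1) + 0.5))


def dequantize_weight(index: int, levels: int = 16) -> float:
    return index / (levels - 1)


def apply_fixed_pattern_noise(network: Network, noise: NoiseModel) -> Network:
    """Perturb the network in place with frozen per-chip parameter scatter.

    Per-neuron g_l and per-driver g_max get lognormal factors (median 1
    times the systematic ``fp_gl_median`` bias for g_l); per-neuron V_th is
    shifted by a Gaussian.  Draws depend only on ``noise.chip_seed`` and
    the network's size, so two builds on the same "chip" coincide.
    """
    rng = np.random.default_rng(noise.chip_seed)
    n, nd = network.n_neurons, network.n_drivers
    # draw in a fixed order regardless of which amplitudes are zero
    z_gl = rng.standard_normal(n)
    z_vth = rng.standard_normal(n)
    z_gmax = rng.standard_normal(nd)
    sig_gl = np.sqrt(np.log1p(noise.fp_gl_cv ** 2))
    sig_gmax = np.sqrt(np.log1p(noise.fp_gmax_cv ** 2))
    for i in range(n):
        p = network.neuron_param(i)
        factor = noise.fp_gl_median * np.exp(sig_gl * z_gl[i])
        new_vth = p.V_th + noise.fp_vth_sd * z_vth[i]
        network.set_neuron_param(i, g_l=p.g_l * factor,
                                 V_th=max(new_vth, p.V_reset))
    for d in range(nd):
        network.driver_g_max[d] *= float(np.exp(sig_gmax * z_gmax[d]))
    network.membrane_noise_sd = noise.membrane_noise_sd
    return network


def enforce_shared_parameters(network: Network, cfg: SubstrateConfig | None = None, *,
                              raise_on_violation: bool = True) -> SubstrateReport:
    """Coerce shared voltage parameters and check resource limits.

    Within each block of ``shared_voltage_group_size`` neurons the voltage
    parameters (E_l, E_exc, E_inh, V_th, V_reset) are forced to the block
    value (taken from the block's first neuron); individually settable
    parameters (g_l, tau_refrac, weights) are untouched.  Resource checks:
    neuron count, fan-in per neuron, number of internal-source drivers,
    total driver count.
    """
    cfg = cfg or SubstrateConfig()
    report = SubstrateReport()
    shared_fields = ("E_l", "E_exc", "E_inh", "V_th", "V_reset")
    gs = cfg.shared_voltage_group_size
    for start in range(0, network.n_neurons, gs):
        block = range(start, min(start + gs, network.n_neurons))
        ref = network.neuron_param(start)
        for nid in block:
            p = network.neuron_param(nid)
            updates = {}
            for f in shared_fields:
                old, new = getattr(p, f), getattr(ref, f)
                if old != new:
                    updates[f] = new
                    report.coercions.append((nid, f, old, new))
            if updates:
                network.set_neuron_param(nid, **updates)

    if network.n_neurons > cfg.n_neurons_total:
        report.violations.append(
            f"{network.n_neurons} neurons exceed capacity {cfg.n_neurons_total}")
    fan_in = network.fan_in()
    if fan_in.size and fan_in.max() > cfg.n_drivers:
        report.violations.append(
            f"fan-in {int(fan_in.max())} exceeds {cfg.n_drivers} synapses per neuron")
    n_int = sum(1 for k in network.driver_source_kind if k == "int")
    if n_int > cfg.max_internal_sources:
        report.violations.append(
            f"{n_int} internal-source drivers exceed {cfg.max_internal_sources}")
    if network.n_drivers > cfg.n_drivers:
        report.violations.append(
            f"{network.n_drivers} drivers exceed {cfg.n_drivers}")
    if report.violations and raise_on_violation:
        raise SubstrateViolation("; ".join(report.violations))
    return report


def quantize_network_weights(network: Network, levels: int = 16) -> None:
    for key, w in list(network._weights.items()):
        q = dequantize_weight(quantize_weight(w, levels), levels)
        if q == 0.0:
            del network._weights[key]
        else:
            network._weights[key] = q


def apply_substrate(network: Network, cfg: SubstrateConfig | None = None) -> SubstrateReport:
    """Full substrate mapping: quantize weights, share parameters, set the
    axonal delay, inject fixed-pattern and trial-to-trial noise."""
    cfg = cfg or SubstrateConfig()
    quantize_network_weights(network, cfg.weight_levels)
    report = enforce_shared_parameters(network, cfg)
    network.delay_ms = cfg.axonal_delay
    apply_fixed_pattern_noise(network, cfg.noise)
    return report
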