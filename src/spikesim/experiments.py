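"""Experiment orchestration: config in, metric report + artifacts out.

One preset per benchmark network.  A run is a pure function of its config
(seeds included), and every report embeds the config hash and seeds needed
to regenerate it.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import numpy as np

from . import io as sio
from .core import SpikeData, simulate
from .metrics import (attractor_stats, cc_pairs, channel_correlation, cv_isi,
                      measure_packets)
from .substrate import NoiseModel, SubstrateConfig, apply_substrate

__all__ = ["run_experiment", "load_preset", "PRESETS"]

PRESETS = ("brn", "swta", "synfire", "synfire_loop", "synfire_filter",
           "attractor", "al", "lsm")


def load_preset(name: str) -> dict:
    ref = resources.files("spikesim.presets") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return sio.load_config(path)


def _substrate_cfg(cfg: dict) -> SubstrateConfig:
    noise_kw = dict(cfg.get("noise", {}))
    noise_kw.setdefault("chip_seed", int(cfg.get("seeds", {}).get("chip", 0)))
    sub_kw = dict(cfg.get("substrate", {}))
    return SubstrateConfig(noise=NoiseModel(**noise_kw), **sub_kw)


def _maybe_substrate(net, cfg: dict):
    if cfg.get("mode", "ideal") == "substrate":
        return apply_substrate(net, _substrate_cfg(cfg))
    return None


# ---------------------------------------------------------------------------
# per-experiment runners


def _run_brn(cfg: dict) -> dict:
    from .networks.brn import brn_stimulus, build_brn, tune_brn_weight

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    T = float(p.get("T_ms", 20_000.0))
    w = p.get("w_exc")
    if w is None:
        w = tune_brn_weight(float(p.get("target_rate", 9.0)), seed=seed)
    net, info = build_brn(seed=seed, w_exc=float(w))
    _maybe_substrate(net, cfg)
    stim = brn_stimulus(info, T, seed=seed + 1)
    out = simulate(net, stim, T, seed=seed + 2)
    ids = np.concatenate([info.exc, info.inh])
    cv, cv_sd, _, excluded = cv_isi(out.spikes, ids)
    cc, cc_sd, _, redrawn = cc_pairs(out.spikes, ids, T=T,
                                     n_pairs=int(p.get("n_pairs", 1000)),
                                     bin_ms=float(p.get("bin_ms", 2.0)),
                                     seed=seed + 3)
    return {"w_exc": w, "mean_rate_hz": len(out.spikes) / ids.size / (T / 1000.0),
            "cv_mean": cv, "cv_sd": cv_sd, "cc_mean": cc, "cc_sd": cc_sd,
            "n_excluded": len(excluded), "n_pairs_redrawn": redrawn,
            "_spikes": out.spikes}


def _run_swta(cfg: dict) -> dict:
    from .networks.swta import crossing_point, sweep_r2

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    r2_values = p.get("r2_values", list(range(0, 101, 10)))
    r2, h1, h2 = sweep_r2(r2_values, r1=float(p.get("r1", 50.0)),
                          n_runs=int(p.get("n_runs", 10)),
                          T=float(p.get("T_ms", 2000.0)), seed=seed)
    return {"r2_values": r2, "rates_half1": h1, "rates_half2": h2,
            "crossing_hz": crossing_point(r2, h1, h2)}


def _run_synfire(cfg: dict, variant: str = "original") -> dict:
    from .networks.synfire import build_synfire, run_packet

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    net, info = build_synfire(variant, n_groups=int(p.get("n_groups", 4)),
                              seed=seed)
    _maybe_substrate(net, cfg)
    a = int(p.get("a", 1))
    sigma = float(p.get("sigma", 1.0))
    T = float(p.get("T_ms", 2000.0 if variant == "loop" else 150.0))
    out = run_packet(net, info, a, sigma, T=T, seed=seed + 1)
    rep: dict = {"variant": variant, "a_stim": a, "sigma_stim": sigma,
                 "_spikes": out.spikes}
    last = info.n_groups - 1 if variant != "loop" else 0
    ms = measure_packets(out.spikes, info.rs_groups[last], group_index=last)
    best = max(ms, key=lambda m: m.n_spikes)
    rep["a_out"] = best.a
    rep["sigma_out"] = best.sigma
    rep["n_traversals"] = len([m for m in ms if m.n_spikes > 0])
    return rep


def _run_attractor(cfg: dict) -> dict:
    from .networks.attractor import (attractor_background, build_attractor,
                                     l4_stimulus)

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    T = float(p.get("T_ms", 5000.0))
    net, info = build_attractor(seed=seed)
    _maybe_substrate(net, cfg)
    stim = attractor_background(info, T, seed=seed + 1)
    cue = p.get("l4_pattern")
    if cue is not None:
        stim = SpikeData.merge([stim, l4_stimulus(info, int(cue),
                                                  int(p.get("l4_minicolumns", 1)),
                                                  T, seed=seed + 2)])
    rec = tuple(int(i) for i in info.patterns[0][:4])
    out = simulate(net, stim, T, seed=seed + 3, record_v=rec)
    rep = attractor_stats(out.spikes, info.patterns, T,
                          traces=out.traces, trace_times=out.trace_times,
                          pattern_of_neuron={int(i): 0 for i in info.patterns[0]})
    return {"active_fraction": rep["active_fraction"],
            "mean_dwell_ms": rep["mean_dwell"],
            "dominant_pattern": rep["dominant_pattern"],
            "up_state_vm": rep.values.get("up_state_vm"),
            "down_state_vm": rep.values.get("down_state_vm"),
            "_spikes": out.spikes}


def _run_al(cfg: dict) -> dict:
    from .networks.antennal_lobe import build_antennal_lobe, run_al_patterns
    from .stimuli import copula_rate_patterns

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    q_values = p.get("q_values", [0.0, 0.25, 0.5, 0.75, 1.0])
    n_patterns = int(p.get("n_patterns", 100))
    rates, emp = copula_rate_patterns(n_patterns, 10,
                                      float(p.get("target_corr", 0.6)),
                                      seed=seed)
    _, (med_in, lo_in, hi_in) = channel_correlation(rates)
    rep = {"input_mean_offdiag": emp, "input_median": med_in,
           "q_values": list(q_values), "output_median": [],
           "output_mean_offdiag": [], "output_p20": [], "output_p80": []}
    for q in q_values:
        net, info = build_antennal_lobe(seed=seed, q=float(q))
        _maybe_substrate(net, cfg)
        _, pn = run_al_patterns(net, info, rates,
                                duration=float(p.get("duration_ms", 1000.0)),
                                seed=seed + 1)
        C, (med, lo, hi) = channel_correlation(pn)
        off = C[~np.eye(C.shape[0], dtype=bool)]
        rep["output_median"].append(med)
        rep["output_mean_offdiag"].append(float(off.mean()))
        rep["output_p20"].append(lo)
        rep["output_p80"].append(hi)
    return rep


def _run_lsm(cfg: dict) -> dict:
    from .networks.lsm import lsm_experiment

    p = cfg.get("params", {})
    seed = int(cfg.get("seeds", {}).get("trial", 0))
    res = lsm_experiment(n_train=int(p.get("n_train", 1000)),
                         n_eval=int(p.get("n_eval", 200)),
                         lag=int(p.get("lag", 1)),
                         jitter_sd=float(p.get("jitter_sd", 1.0)),
                         seed=seed)
    return {"accuracy": res["accuracy"], "lag": res["lag"],
            "mean_liquid_rate_hz": res["mean_liquid_rate"],
            "n_train": res["n_train"], "n_eval": res["n_eval"],
            "final_train_error": float(np.mean(res["train_errors"][-100:]))}


_RUNNERS = {
    "brn": _run_brn,
    "swta": _run_swta,
    "synfire": lambda cfg: _run_synfire(cfg, "original"),
    "synfire_loop": lambda cfg: _run_synfire(cfg, "loop"),
    "synfire_filter": lambda cfg: _run_synfire(cfg, "filter"),
    "attractor": _run_attractor,
    "al": _run_al,
    "lsm": _run_lsm,
}


def run_experiment(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Build, stimulate, simulate, and measure one benchmark network.

    ``cfg`` needs an ``experiment`` key naming a preset runner; everything
    else (mode, seeds, params, substrate, noise) is optional.  When
    ``out_dir`` is given, spike files, the report (JSON), and a config
    snapshot are written there.
    """
    name = cfg.get("experiment")
    if name not in _RUNNERS:
        raise ValueError(f"unknown experiment {name!r}; choose from {PRESETS}")
    if cfg.get("mode", "ideal") not in ("ideal", "substrate"):
        raise ValueError("mode must be 'ideal' or 'substrate'")
    report = _RUNNERS[name](cfg)
    spikes = report.pop("_spikes", None)
    report["experiment"] = name
    report["mode"] = cfg.get("mode", "ideal")
    report["seeds"] = dict(cfg.get("seeds", {}))
    report["config_hash"] = sio.config_hash(cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if spikes is not None:
            sio.write_spikes(out / f"{name}_spikes.txt", spikes,
                             header={"experiment": name,
                                     "config_hash": report["config_hash"]})
        sio.write_report(out / f"{name}_report.json", report)
        sio.save_config(out / f"{name}_config.yaml", cfg)
    return report
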