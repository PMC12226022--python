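"""Orchestrated generate -> simulate -> analyze -> report pipeline.

A single master seed is fanned out per stage through numpy's SeedSequence
(child i = SeedSequence(master).spawn()[i], reduced mod 2**31), so re-running
with the same configuration is bit-identical while stages stay independently
reseedable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblies as asm
from . import controls, io, metrics, topology
from .config import PipelineConfig, dump_config
from .plasticity import (DriverKernels, PathwayEndpoints, PlasticityParams,
                         derive_thresholds, measure_c_pre_c_post, simulate)
from .synthetic import (PlantedGroup, build_presentations, gen_network,
                        gen_patterns, gen_planted_activity, gen_stimulus_spikes,
                        gen_synapses, init_synapse_states)

logger = logging.getLogger(__name__)

__all__ = ["stage_seeds", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _params_from_config(cfg: PipelineConfig) -> tuple[PlasticityParams, DriverKernels]:
    pc, kc = cfg.plasticity, cfg.kernels
    params = PlasticityParams(
        tau_rho_s=pc.tau_rho_s, rho_star=pc.rho_star, gamma_d=pc.gamma_d,
        gamma_p=pc.gamma_p, eta=pc.eta, spine_volume_um3=pc.spine_volume_um3,
        ca_rest_uM=pc.ca_rest_uM, tau_ca_ms=pc.tau_ca_ms, e_nmda_mV=pc.e_nmda_mV,
        mg_theta=pc.mg_theta, mg_kappa=pc.mg_kappa, mg_out_mM=pc.mg_out_mM,
        tau_star_ms=pc.tau_star_ms, tau_change_s=pc.tau_change_s,
        endpoints=PathwayEndpoints(u_se_scale=pc.u_se_scale),
    )
    kernels = DriverKernels(**kc.model_dump())
    return params, kernels


def _innervation_groups(network, schedule, seed, group_size=12):
    """Per-pattern planted co-firing groups (deterministic stand-in for the
    feed-forward thalamic innervation): each pattern drives a neuron group
    whose overlap mirrors the patterns' fiber overlap."""
    rng = np.random.default_rng(seed)
    neurons = network.nodes["node_id"].to_numpy()
    n_fib = schedule.n_fibers
    targets = {f: rng.choice(neurons, size=max(1, len(neurons) // 10), replace=False)
               for f in range(n_fib)}
    plan = []
    for lab in sorted(schedule.patterns):
        votes: dict = {}
        for f in schedule.patterns[lab]:
            for n in targets[f]:
                votes[int(n)] = votes.get(int(n), 0) + 1
        top = sorted(votes, key=lambda n: (-votes[n], n))[:group_size]
        plan.append(PlantedGroup(pattern=lab, neurons=tuple(top),
                                 window_ms=(0.0, 100.0), rate_hz=40.0))
    return plan


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns a dict of output paths and summary values."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    g = cfg.generator
    params, kernels = _params_from_config(cfg)
    result: dict = {"out_dir": str(out)}
    t_wall = time.time()

    stage = "generate"
    try:
        network = gen_network(g.n_nodes, conn_prob_fn=lambda a, b: g.conn_prob,
                              seed=seeds[0])
        syn = gen_synapses(network, g.mean_syn_per_conn, g.sd_syn_per_conn,
                           seed=seeds[1])
        schedule = gen_patterns(n_bundles=g.n_bundles, base_fraction=g.base_fraction,
                                n_fibers=g.n_fibers, seed=seeds[2])
        build_presentations(schedule, n_repetitions=g.n_repetitions, isi_ms=g.isi_ms,
                            seed=seeds[2])
        fiber_spikes = gen_stimulus_spikes(schedule, rate_max_hz=g.rate_max_hz,
                                           stim_duration_ms=g.stim_duration_ms,
                                           seed=seeds[3])
        plan = _innervation_groups(network, schedule, seeds[4])
        duration = cfg.plasticity.duration_ms
        spikes, _ = gen_planted_activity(network, schedule, plan,
                                         noise_rate_hz=g.noise_rate_hz,
                                         duration_ms=duration, seed=seeds[5])
        spikes = {k: v[v < duration] for k, v in spikes.items()}
        syn = init_synapse_states(syn, g.p_potentiated, network.layer_of(),
                                  endpoints=params.endpoints, seed=seeds[6])
        c_pre, c_post = measure_c_pre_c_post(syn, kernels, params)
        syn["c_pre"], syn["c_post"] = c_pre, c_post
        syn["theta_d"], syn["theta_p"] = derive_thresholds(
            c_pre, c_post, syn["neurite_kind"], params, plastic=syn["plastic"])
        io.write_network(network, out / "edges.txt", out / "nodes.tsv", seed=cfg.seed)
        io.write_synapses(syn, out / "synapses.tsv", seed=cfg.seed)
        io.write_schedule(schedule, out / "schedule.json", seed=cfg.seed)
        io.write_spikes(spikes, out / "spikes.tsv", seed=cfg.seed)
    except Exception as e:  # noqa: BLE001 - typed re-raise naming the stage
        raise PipelineError(stage, e) from e

    stage = "simulate"
    try:
        if cfg.analysis_only and cfg.trace_path:
            trace = io.read_trace(cfg.trace_path)
        else:
            trace = simulate(syn, spikes, duration_ms=cfg.plasticity.duration_ms,
                             kernels=kernels, params=params,
                             report_dt_ms=cfg.plasticity.report_dt_ms,
                             dt_ms=cfg.plasticity.dt_ms)
            io.write_trace(trace, out / "trace.h5", seed=cfg.seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "analyze"
    try:
        report: dict = {"config": json.loads(json.dumps(cfg.model_dump(), sort_keys=True))}
        if cfg.analysis.run_changes and trace.rho.shape[1] >= 2:
            cs = metrics.change_summary(trace, syn, tolerance=cfg.analysis.change_tolerance)
            report["changes"] = {
                "fractions_synapse": cs.fractions_synapse.round(6).to_dict(),
                "fractions_connection": cs.fractions_connection.round(6).to_dict(),
                "n_crossings_up": int(len(cs.crossing_times_up)),
                "n_crossings_down": int(len(cs.crossing_times_down)),
            }
            l2 = controls.change_norm_series(trace.rho, reference="t0")
            report["changes"]["l2_from_t0_final"] = float(l2[-1])
        if cfg.analysis.run_assemblies:
            try:
                res, binned = asm.detect_assemblies(
                    spikes, bin_ms=cfg.analysis.bin_ms,
                    k_range=range(cfg.analysis.k_min, cfg.analysis.k_max_clusters + 1),
                    seed=seeds[7])
                report["assemblies"] = {
                    "n_clusters": int(res.n_clusters),
                    "n_assemblies": len(res.assemblies),
                    "sizes": {str(k): len(v) for k, v in sorted(res.assemblies.items())},
                }
            except ValueError as e:
                report["assemblies"] = {"skipped": str(e)}
        if cfg.analysis.run_topology:
            counts = topology.simplex_counts(network.edges,
                                             max_dim=cfg.analysis.k_max_simplices)
            report["topology"] = {"simplex_counts": counts.tolist()}
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        md = ["# plastinet run report", "",
              f"- nodes: {network.n_nodes}, edges: {network.n_edges}, synapses: {len(syn)}",
              f"- duration: {cfg.plasticity.duration_ms} ms, dt: {cfg.plasticity.dt_ms} ms"]
        for k, v in report.items():
            if k != "config":
                md.append(f"- {k}: {json.dumps(v, sort_keys=True)}")
        (out / "report.md").write_text("\n".join(md) + "\n")
        (out / "config.yaml").write_text(dump_config(cfg))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    result["report"] = report
    result["wall_s"] = time.time() - t_wall
    return result
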