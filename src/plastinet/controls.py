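"""Null and control models for the plasticity analyses.

Pair-based STDP rule (the classic exponential-window rule) as a
change-magnitude control for the calcium-based model; a K-dimensional
random-walk control for global/noise-driven drift of the efficacy vector;
rate-matched neuron controls for assembly analyses; and a degree-preserving
random "changing subgraph" control for the topology analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "STDPParams",
    "RandomWalkSpec",
    "stdp_weight_changes",
    "change_norm_series",
    "fit_step_size",
    "random_walk_displacement",
    "rate_matched_control",
    "random_changing_subgraph",
]


@dataclass
class STDPParams:
    a_plus: float = 0.05
    a_minus: float = 0.05
    tau_plus_ms: float = 20.0
    tau_minus_ms: float = 20.0
    pairing_scheme: str = "all_to_all"  # or "nearest_neighbor"

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.tau_plus_ms <= 0 or self.tau_minus_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.pairing_scheme not in ("all_to_all", "nearest_neighbor"):
            raise ValueError("unknown pairing scheme")


@dataclass
class RandomWalkSpec:
    """K changing connections, each moving ±epsilon per step; step norm
    l = epsilon * sqrt(K) exactly."""

    k: int
    epsilon: float
    n_steps: int

    def __post_init__(self):
        if self.k < 1 or self.n_steps < 0:
            raise ValueError("K must be >= 1 and N >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @property
    def step_norm(self) -> float:
        return self.epsilon * np.sqrt(self.k)


def stdp_weight_changes(pre_spikes, post_spikes, params: STDPParams | None = None) -> pd.DataFrame:
    """Per-event weight updates of the pair-based STDP rule.

    Potentiation Δw+ = A+ exp(-Δt/τ+) is applied at each postsynaptic spike
    (over all earlier presynaptic spikes, or only the most recent one under the
    nearest-neighbour scheme); depression Δw- = -A- exp(Δt/τ-) with
    Δt = t_post - t_pre < 0 is applied at each presynaptic spike over earlier
    postsynaptic spikes.  A pre and post spike at the same instant counts as a
    causal (potentiating) pair with Δt = 0.  Returns a time-ordered table with
    columns (time, delta_w, kind, w) where w is the cumulative weight starting
    from 0; weights are unbounded (no clipping).
    """
    p = params or STDPParams()
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if np.any(np.diff(pre) < 0) or np.any(np.diff(post) < 0):
        raise ValueError("spike trains must be sorted")
    events = []  # (time, order, kind)  pre processed before post at equal times
    events += [(t, 0, "pre") for t in pre]
    events += [(t, 1, "post") for t in post]
    events.sort()
    nn = p.pairing_scheme == "nearest_neighbor"

    trace_pre = 0.0   # sum of exp(-(t - t_pre)/tau+) over past pre spikes
    trace_post = 0.0  # same for post spikes with tau-
    last_pre = None
    last_post = None
    t_prev = None
    rows = []
    for t, _, kind in events:
        if t_prev is not None and t > t_prev:
            dt = t - t_prev
            trace_pre *= np.exp(-dt / p.tau_plus_ms)
            trace_post *= np.exp(-dt / p.tau_minus_ms)
        t_prev = t
        if kind == "post":
            if nn:
                dw = p.a_plus * np.exp(-(t - last_pre) / p.tau_plus_ms) if last_pre is not None else 0.0
            else:
                dw = p.a_plus * trace_pre
            if dw != 0.0:
                rows.append((t, dw, "potentiation"))
            trace_post += 1.0
            last_post = t
        else:
            if nn:
                dw = -p.a_minus * np.exp(-(t - last_post) / p.tau_minus_ms) if last_post is not None else 0.0
            else:
                dw = -p.a_minus * trace_post
            if dw != 0.0:
                rows.append((t, dw, "depression"))
            trace_pre += 1.0
            last_pre = t
    df = pd.DataFrame(rows, columns=["time", "delta_w", "kind"])
    df["w"] = df["delta_w"].cumsum() if len(df) else pd.Series(dtype=float)
    return df


def change_norm_series(trace: np.ndarray, reference="previous",
                       times=None) -> np.ndarray:
    """L2 norm over synapses of the state change at each report time.

    ``trace``: (S, R) state matrix.  ``reference`` selects the comparison
    state: "previous" (per-step change, R-1 values), "t0" (change from the
    first report), or an integer column index (e.g. the 5-minute mark).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 2:
        raise ValueError("trace must be (synapses, report_times)")
    if reference == "previous":
        return np.linalg.norm(np.diff(x, axis=1), axis=0)
    if reference == "t0":
        ref = x[:, [0]]
    elif isinstance(reference, (int, np.integer)):
        ref = x[:, [int(reference)]]
    else:
        raise ValueError("reference must be 'previous', 't0' or a column index")
    return np.linalg.norm(x - ref, axis=0)


def fit_step_size(trace: np.ndarray, report_times_s: np.ndarray,
                  t_min_s: float = 300.0) -> float:
    """Average per-report-step L2 change after ``t_min_s`` (default 5 min)."""
    t = np.asarray(report_times_s, dtype=float)
    x = np.asarray(trace, dtype=float)
    sel = np.nonzero(t > t_min_s)[0]
    if len(sel) < 2:
        raise ValueError("need at least 2 report times after t_min")
    steps = np.linalg.norm(np.diff(x[:, sel], axis=1), axis=0)
    return float(steps.mean())


def random_walk_displacement(spec: RandomWalkSpec, seed: int = 0,
                             mode: str = "simulate") -> np.ndarray:
    """Distance from the origin, ‖R(n)‖, for n = 0..N.

    simulate: every coordinate moves ±epsilon with equal probability each step
    (per-step norm exactly epsilon*sqrt(K)); analytic: the diffusive
    approximation l*sqrt(n).
    """
    if mode == "analytic":
        return spec.step_norm * np.sqrt(np.arange(spec.n_steps + 1, dtype=float))
    if mode != "simulate":
        raise ValueError("mode must be 'simulate' or 'analytic'")
    rng = np.random.default_rng(seed)
    r = np.zeros(spec.k)
    out = np.empty(spec.n_steps + 1)
    out[0] = 0.0
    for n in range(1, spec.n_steps + 1):
        r += spec.epsilon * (2.0 * rng.integers(0, 2, size=spec.k) - 1.0)
        out[n] = np.linalg.norm(r)
    return out


def rate_matched_control(assembly_neurons, population_rates: pd.Series, seed: int = 0,
                         n_strata: int = 10) -> tuple[np.ndarray, bool]:
    """Random neuron set matching an assembly's size and firing-rate distribution.

    Stratified sampling without replacement on the deciles of the assembly's
    rate distribution; assembly members are excluded unless a stratum cannot be
    filled without them, in which case the result is flagged.
    Returns (control_ids, flagged).
    """
    assembly = np.asarray(list(assembly_neurons))
    if assembly.size == 0:
        raise ValueError("assembly is empty")
    rates = population_rates.astype(float)
    missing = set(assembly.tolist()) - set(rates.index.tolist())
    if missing:
        raise ValueError(f"rates missing for neurons: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    arates = rates.loc[assembly]
    qs = np.quantile(arates, np.linspace(0, 1, n_strata + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    member = rates.index.isin(assembly)
    chosen: list = []
    flagged = False
    for i in range(n_strata):
        need = int(((arates >= qs[i]) & (arates < qs[i + 1])).sum()) if i < n_strata - 1 \
            else int(((arates >= qs[i]) & (arates <= qs[i + 1])).sum())
        if need == 0:
            continue
        in_stratum = (rates >= qs[i]) & (rates < qs[i + 1] if i < n_strata - 1 else rates <= qs[i + 1])
        pool = rates.index[in_stratum & ~member & ~rates.index.isin(chosen)].to_numpy()
        if len(pool) < need:
            flagged = True
            extra = rates.index[in_stratum & ~rates.index.isin(chosen)].to_numpy()
            pool = extra
        if len(pool) < need:  # stratum simply too small: borrow nearest rates
            flagged = True
            remaining = rates.index[~rates.index.isin(chosen)].to_numpy()
            stratum_mid = 0.5 * (np.nan_to_num(qs[i], neginf=rates.min()) +
                                 np.nan_to_num(qs[i + 1], posinf=rates.max()))
            order = np.argsort(np.abs(rates.loc[remaining].to_numpy() - stratum_mid))
            pool = remaining[order[:need]]
            chosen.extend(pool.tolist())
            continue
        chosen.extend(rng.choice(pool, size=need, replace=False).tolist())
    control = np.asarray(chosen[: len(assembly)])
    if len(control) != len(assembly):
        raise RuntimeError("failed to assemble a size-matched control")
    if flagged:
        logger.warning("rate-matched control includes assembly members or borrowed rates")
    return control, flagged


def random_changing_subgraph(changing_edges, network_edges, seed: int = 0) -> np.ndarray:
    """Random control for a changing subgraph: same number of edges, sampled
    uniformly among all network edges between the changing subgraph's nodes.

    Preserves the node set and the edge count, hence identical 0- and 1-simplex
    counts to the changing subgraph.
    """
    changing = np.asarray(list(changing_edges), dtype=np.int64).reshape(-1, 2)
    all_edges = np.asarray(list(network_edges), dtype=np.int64).reshape(-1, 2)
    edge_set = {tuple(e) for e in all_edges.tolist()}
    for e in changing.tolist():
        if tuple(e) not in edge_set:
            raise ValueError(f"changing edge {tuple(e)} not in the network")
    nodes = set(changing.ravel().tolist())
    cand = np.array([e for e in all_edges.tolist() if e[0] in nodes and e[1] in nodes],
                    dtype=np.int64).reshape(-1, 2)
    if len(cand) < len(changing):
        raise ValueError("not enough candidate edges among the changing subgraph's nodes")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(cand), size=len(changing), replace=False)
    return cand[np.sort(pick)]
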