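"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate, at desk scale, the structure of a cortical-column
microcircuit experiment: a directed excitatory network with layer labels and
positions in a cylindrical volume, multi-synapse connections placed on abstract
dendritic branches, thalamic input fibers organised into 10 overlapping
stimulus patterns (4 disjoint base patterns A-D and their unions E-J), stimulus
and background spike trains, and bimodal initial synaptic efficacies
(every synapse starts at one of the two fixed points, rho = 0 or rho = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "StimulusSchedule",
    "SpikeTrains",
    "PlantedGroup",
    "gen_network",
    "gen_synapses",
    "gen_fiber_locations",
    "gen_patterns",
    "build_presentations",
    "rate_profile",
    "gen_stimulus_spikes",
    "gen_planted_activity",
    "init_synapse_states",
    "SYNAPSE_COLUMNS",
]

#: columns of the tabular synapse representation
SYNAPSE_COLUMNS = [
    "syn_id", "pre", "post", "branch_id", "path_offset", "neurite_kind",
    "rho", "U_SE", "g_AMPA_hat", "g_NMDA_hat",
    "c_pre", "c_post", "theta_d", "theta_p", "plastic",
]


@dataclass
class DirectedNetwork:
    """Directed simple graph with per-node layer labels and 3-D positions (µm)."""

    nodes: pd.DataFrame  # columns: node_id, layer, x, y, z
    edges: np.ndarray    # (E, 2) int array of (pre, post)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        ids = set(self.nodes["node_id"].tolist())
        if self.edges.size:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            if len({tuple(e) for e in self.edges.tolist()}) != len(self.edges):
                raise ValueError("duplicate edges")
            endpoints = set(self.edges.ravel().tolist())
            if not endpoints <= ids:
                raise ValueError("edge endpoint not among declared nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def layer_of(self) -> dict:
        return dict(zip(self.nodes["node_id"], self.nodes["layer"]))


@dataclass
class StimulusSchedule:
    """Thalamic fiber layout, pattern definitions and presentation schedule."""

    fiber_locations: np.ndarray              # (F, 2) flat-map coordinates
    bundle_of: np.ndarray                    # (F,) bundle index per fiber
    patterns: dict                           # label -> frozenset of fiber ids
    pattern_bundles: dict                    # label -> frozenset of bundle ids
    base_labels: tuple = ("A", "B", "C", "D")
    presentations: list = field(default_factory=list)  # [(label, onset_ms), ...]
    isi_ms: float = 500.0
    stim_duration_ms: float = 100.0
    nonspecific_fibers: frozenset = frozenset()

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_locations)

    def pattern_indicator(self, label: str) -> np.ndarray:
        v = np.zeros(self.n_fibers, dtype=bool)
        v[list(self.patterns[label])] = True
        return v


class SpikeTrains(dict):
    """Mapping source_id -> strictly increasing spike times (ms)."""

    def __setitem__(self, key, value):
        t = np.asarray(value, dtype=float)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError(f"spike train {key} must be non-negative and strictly increasing")
        super().__setitem__(key, t)

    def merged_with(self, other: "SpikeTrains") -> "SpikeTrains":
        out = SpikeTrains()
        for k in set(self) | set(other):
            t = np.concatenate([self.get(k, np.empty(0)), other.get(k, np.empty(0))])
            t = np.unique(t)  # sorted, deduplicated
            out[k] = t
        return out

    def total_spikes(self) -> int:
        return int(sum(len(v) for v in self.values()))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

#: depth extent (µm) of the cortical-column-like cylinder, layer 1 at the top
_COLUMN_DEPTH = 1500.0
_COLUMN_RADIUS = 250.0


def gen_network(
    n_nodes: int,
    layer_fractions: Mapping[int, float] | None = None,
    conn_prob_fn: Callable[[pd.Series, pd.Series], float] | None = None,
    seed: int = 0,
    radius: float = _COLUMN_RADIUS,
    depth: float = _COLUMN_DEPTH,
) -> DirectedNetwork:
    """Sample a directed network in a cylindrical column with layer-stratified depth.

    ``conn_prob_fn(pre_row, post_row)`` maps the two node attribute rows to a
    connection probability; every ordered pair (no self-pairs) is sampled
    independently, so the expected edge count is the sum of the pairwise
    probabilities.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if layer_fractions is None:
        layer_fractions = {l: 1 / 6 for l in range(1, 7)}
    fr = np.array([layer_fractions.get(l, 0.0) for l in range(1, 7)], dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("layer_fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)

    # layer assignment by exact proportions (remainders to the largest fractions)
    counts = np.floor(fr * n_nodes).astype(int)
    rem = n_nodes - counts.sum()
    order = np.argsort(-(fr * n_nodes - counts))
    counts[order[:rem]] += 1
    layers = np.repeat(np.arange(1, 7), counts)

    # positions: uniform disc cross-section, depth stratified by layer
    bounds = np.concatenate([[0.0], np.cumsum(fr)]) * depth
    r = radius * np.sqrt(rng.uniform(size=n_nodes))
    phi = rng.uniform(0, 2 * np.pi, size=n_nodes)
    z = np.array([rng.uniform(bounds[l - 1], bounds[l]) for l in layers])
    nodes = pd.DataFrame(
        {"node_id": np.arange(n_nodes), "layer": layers,
         "x": r * np.cos(phi), "y": r * np.sin(phi), "z": z}
    )

    if conn_prob_fn is None:
        conn_prob_fn = lambda a, b: 0.05
    rows = list(nodes.itertuples(index=False))
    edges = []
    for i, a in enumerate(rows):
        for j, b in enumerate(rows):
            if i == j:
                continue
            p = float(conn_prob_fn(a, b))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {p} outside [0, 1]")
            if rng.uniform() < p:
                edges.append((i, j))
    return DirectedNetwork(nodes=nodes, edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2))


def expected_edge_count(network_nodes: pd.DataFrame, conn_prob_fn) -> tuple[float, float]:
    """Analytic mean and variance of the edge count under independent sampling."""
    rows = list(network_nodes.itertuples(index=False))
    mean = var = 0.0
    for i, a in enumerate(rows):
        for j, b in enumerate(rows):
            if i == j:
                continue
            p = float(conn_prob_fn(a, b))
            mean += p
            var += p * (1 - p)
    return mean, var


# ---------------------------------------------------------------------------
# synapses on abstract dendritic branches
# ---------------------------------------------------------------------------

def _nsyn_distribution_params(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (r, p) of the shifted negative binomial 1 + NB(r, p)."""
    m = mean - 1.0
    v = sd * sd
    if m <= 0:
        raise ValueError("mean_syn_per_conn must be > 1 for a stochastic count law")
    if v <= m:  # under-dispersed: fall back to (truncated) Poisson shape
        return np.inf, m
    p = m / v
    r = m * p / (1 - p)
    return r, p


def _sample_nsyn(rng, n: int, mean: float, sd: float, n_max: int = 20) -> np.ndarray:
    """Per-connection synapse counts: shifted, truncated count distribution.

    1 + NegativeBinomial(r, p) truncated to [1, n_max], moment-matched to the
    requested mean/SD (a shifted geometric is the r = 1 special case but cannot
    reach SD 2.3 at mean 4.1, hence the extra dispersion parameter).
    """
    if sd == 0:
        if abs(mean - round(mean)) > 1e-9:
            raise ValueError("sd=0 requires an integer mean")
        return np.full(n, int(round(mean)), dtype=np.int64)
    r, p = _nsyn_distribution_params(mean, sd)
    if np.isinf(r):
        counts = 1 + rng.poisson(p, size=n)
    else:
        counts = 1 + rng.negative_binomial(r, p, size=n)
    return np.clip(counts, 1, n_max).astype(np.int64)


@dataclass
class BranchModel:
    """Abstract dendritic branches: straight 1-D segments per postsynaptic neuron."""

    n_branches: int = 10
    branch_length_um: float = 200.0
    p_apical_by_layer: Mapping[int, float] = field(
        default_factory=lambda: {l: 0.3 for l in range(1, 7)}
    )


def gen_synapses(
    network: DirectedNetwork,
    mean_syn_per_conn: float = 4.1,
    sd_syn_per_conn: float = 2.3,
    branch_model: BranchModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place synapses for every connection on abstract dendritic branches.

    Every edge receives at least one synapse; per-connection counts follow the
    truncated shifted count law (default moments 4.1 / 2.3 synapses per
    connection).  Each synapse gets a branch of the postsynaptic neuron, a path
    offset (µm from branch origin) and an apical/basal label drawn from the
    post-layer mixture.  Plasticity-state columns are initialised to NaN and
    filled by ``init_synapse_states`` / threshold derivation.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    bm = branch_model or BranchModel()
    rng = np.random.default_rng(seed)
    layer_of = network.layer_of()

    nsyn = _sample_nsyn(rng, network.n_edges, mean_syn_per_conn, sd_syn_per_conn)
    pre = np.repeat(network.edges[:, 0], nsyn)
    post = np.repeat(network.edges[:, 1], nsyn)
    n = len(pre)

    # branches are identified per (post neuron, local index); apical/basal is a
    # property of the branch, so all synapses on one branch share the label
    local_branch = rng.integers(0, bm.n_branches, size=n)
    branch_id = post * bm.n_branches + local_branch
    post_layers = np.array([layer_of[p] for p in post])
    p_apical = np.array([bm.p_apical_by_layer.get(int(l), 0.3) for l in post_layers])
    # hash-free deterministic per-branch draw: one uniform per (post, branch)
    branch_keys, inv = np.unique(branch_id, return_inverse=True)
    u = rng.uniform(size=len(branch_keys))
    # apical probability of the branch taken from its neuron's layer (first occurrence)
    first_idx = np.zeros(len(branch_keys), dtype=int)
    seen = {}
    for i, b in enumerate(branch_id):
        if b not in seen:
            seen[b] = i
    first_idx = np.array([seen[b] for b in branch_keys])
    apical_branch = u < p_apical[first_idx]
    neurite = np.where(apical_branch[inv], "apical", "basal")

    offsets = rng.uniform(0.0, bm.branch_length_um, size=n)

    df = pd.DataFrame(
        {
            "syn_id": np.arange(n, dtype=np.int64),
            "pre": pre,
            "post": post,
            "branch_id": branch_id.astype(np.int64),
            "path_offset": offsets,
            "neurite_kind": neurite,
            "rho": np.nan,
            "U_SE": np.nan,
            "g_AMPA_hat": np.nan,
            "g_NMDA_hat": np.nan,
            "c_pre": np.nan,
            "c_post": np.nan,
            "theta_d": np.nan,
            "theta_p": np.nan,
            "plastic": True,
        }
    )
    return df


# ---------------------------------------------------------------------------
# stimulus patterns
# ---------------------------------------------------------------------------

def gen_fiber_locations(n_fibers: int = 1000, seed: int = 0, extent: float = 1.0) -> np.ndarray:
    """Uniform 2-D flat-map locations for thalamic fibers."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, extent, size=(n_fibers, 2))


def gen_patterns(
    n_bundles: int = 100,
    base_fraction: float = 0.12,
    n_fibers: int = 1000,
    seed: int = 0,
    fiber_locations: np.ndarray | None = None,
) -> StimulusSchedule:
    """Build the 10 stimulus patterns A..J over k-means fiber bundles.

    Base patterns A-D are four disjoint random groups of
    ``floor(base_fraction * n_bundles)`` bundles each; E, F, G are pairwise
    unions of two bases, H and I unions of three, and J the union of all four.
    """
    n_base = int(np.floor(base_fraction * n_bundles))
    if 4 * n_base > n_bundles:
        raise ValueError("base_fraction too large: four disjoint base groups must fit")
    if n_base < 1:
        raise ValueError("base_fraction too small: empty base patterns")
    rng = np.random.default_rng(seed)
    if fiber_locations is None:
        fiber_locations = gen_fiber_locations(n_fibers, seed=seed)
    km = KMeans(n_clusters=n_bundles, n_init=4, random_state=int(rng.integers(2**31 - 1)))
    bundle_of = km.fit_predict(fiber_locations)

    perm = rng.permutation(n_bundles)
    bases = {
        lab: frozenset(perm[i * n_base:(i + 1) * n_base].tolist())
        for i, lab in enumerate("ABCD")
    }
    combos = {
        "E": ("A", "B"), "F": ("B", "C"), "G": ("C", "D"),
        "H": ("A", "B", "C"), "I": ("A", "B", "D"),
        "J": ("A", "B", "C", "D"),
    }
    pattern_bundles = dict(bases)
    for lab, parts in combos.items():
        pattern_bundles[lab] = frozenset().union(*(bases[p] for p in parts))
    patterns = {
        lab: frozenset(np.nonzero(np.isin(bundle_of, list(bs)))[0].tolist())
        for lab, bs in pattern_bundles.items()
    }
    return StimulusSchedule(
        fiber_locations=np.asarray(fiber_locations, float),
        bundle_of=np.asarray(bundle_of, int),
        patterns=patterns,
        pattern_bundles=pattern_bundles,
    )


def pattern_overlap(schedule: StimulusSchedule, lab_a: str, lab_b: str) -> float:
    """Shared-fiber fraction of two equal-size patterns: |A∩B| / max(|A|, |B|)."""
    a, b = schedule.patterns[lab_a], schedule.patterns[lab_b]
    return len(a & b) / max(len(a), len(b))


def build_presentations(
    schedule: StimulusSchedule,
    n_repetitions: int = 10,
    isi_ms: float = 500.0,
    t_start_ms: float = 0.0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> StimulusSchedule:
    """Balanced random presentation order: each block presents every pattern once."""
    rng = np.random.default_rng(seed)
    labels = list(labels) if labels is not None else sorted(schedule.patterns)
    pres = []
    t = t_start_ms
    for _ in range(n_repetitions):
        for lab in rng.permutation(labels):
            pres.append((str(lab), float(t)))
            t += isi_ms
    schedule.presentations = pres
    schedule.isi_ms = isi_ms
    return schedule


# ---------------------------------------------------------------------------
# stimulus spike trains
# ---------------------------------------------------------------------------

def rate_profile(
    t_ms: np.ndarray,
    rate_max_hz: float = 17.5,
    rise_ms: float = 10.0,
    adapt_tau_ms: float = 50.0,
    stim_duration_ms: float = 100.0,
) -> np.ndarray:
    """Stimulus firing-rate profile: linear rise to ``rate_max_hz``, then
    exponential adaptation, zero outside the stimulation window."""
    t = np.asarray(t_ms, dtype=float)
    r = np.where(
        t < rise_ms,
        rate_max_hz * t / rise_ms,
        rate_max_hz * np.exp(-(t - rise_ms) / adapt_tau_ms),
    )
    r[(t < 0) | (t >= stim_duration_ms)] = 0.0
    return r


def _inhom_poisson(rng, onset_ms, rate_max_hz, rise_ms, adapt_tau_ms, dur_ms) -> np.ndarray:
    """Thinning sampler for the parametric stimulus profile (one fiber, one stim)."""
    n = rng.poisson(rate_max_hz / 1000.0 * dur_ms)  # candidates at the peak rate
    cand = np.sort(rng.uniform(0.0, dur_ms, size=n))
    keep = rng.uniform(0, rate_max_hz, size=n) < rate_profile(
        cand, rate_max_hz, rise_ms, adapt_tau_ms, dur_ms
    )
    return onset_ms + cand[keep]


def gen_stimulus_spikes(
    schedule: StimulusSchedule,
    rate_max_hz: float = 17.5,
    stim_duration_ms: float = 100.0,
    rise_ms: float = 10.0,
    adapt_tau_ms: float = 50.0,
    seed: int = 0,
    nonspecific_fraction: float = 0.1,
) -> SpikeTrains:
    """Spike trains for every fiber across the presentation schedule.

    Fibers of the active pattern emit an inhomogeneous Poisson train whose rate
    rises linearly (10 ms) to ``rate_max_hz`` and adapts exponentially
    (tau = 50 ms) within the stimulation window; other fibers are silent.  A
    nonspecific fiber group (ids beyond the patterned fibers) is active at
    every presentation with half the maximal rate.
    """
    if not schedule.presentations:
        raise ValueError("schedule has no presentations")
    if rate_max_hz <= 0:
        raise ValueError("rate_max_hz must be > 0")
    rng = np.random.default_rng(seed)
    n_fib = schedule.n_fibers
    n_nonspec = int(round(nonspecific_fraction * n_fib))
    nonspec = frozenset(range(n_fib, n_fib + n_nonspec))
    schedule.nonspecific_fibers = nonspec
    schedule.stim_duration_ms = stim_duration_ms

    spikes = {f: [] for f in range(n_fib + n_nonspec)}
    for lab, onset in schedule.presentations:
        for f in schedule.patterns[lab]:
            spikes[f].append(
                _inhom_poisson(rng, onset, rate_max_hz, rise_ms, adapt_tau_ms, stim_duration_ms)
            )
        for f in nonspec:
            spikes[f].append(
                _inhom_poisson(rng, onset, rate_max_hz / 2.0, rise_ms, adapt_tau_ms, stim_duration_ms)
            )
    out = SpikeTrains()
    for f, chunks in spikes.items():
        t = np.sort(np.concatenate(chunks)) if chunks else np.empty(0)
        out[f] = np.unique(t)
    return out


# ---------------------------------------------------------------------------
# planted assembly activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGroup:
    """One planted co-firing group: neurons firing in a latency window of a pattern."""

    pattern: str
    neurons: tuple
    window_ms: tuple  # (start, end) relative to pattern onset
    rate_hz: float = 100.0


def gen_planted_activity(
    network: DirectedNetwork,
    schedule: StimulusSchedule,
    assembly_plan: Sequence[PlantedGroup],
    noise_rate_hz: float = 1.0,
    duration_ms: float | None = None,
    seed: int = 0,
) -> tuple[SpikeTrains, list]:
    """Spike trains with planted assembly sequences plus Poisson background.

    Each presentation of a pattern activates the plan's groups for that
    pattern: group members fire Poisson at ``rate_hz`` inside their latency
    window.  All neurons additionally fire background Poisson at
    ``noise_rate_hz``.  Returns the trains and the plan (ground truth for
    recovery scoring).
    """
    if not schedule.presentations:
        raise ValueError("schedule has no presentations")
    by_pattern: dict[str, list[PlantedGroup]] = {}
    for g in assembly_plan:
        ws = by_pattern.setdefault(g.pattern, [])
        for other in ws:
            if set(other.neurons) & set(g.neurons):
                a0, a1 = other.window_ms
                b0, b1 = g.window_ms
                if a0 < b1 and b0 < a1:
                    raise ValueError("overlapping latency windows for one group")
        ws.append(g)

    rng = np.random.default_rng(seed)
    if duration_ms is None:
        duration_ms = max(t for _, t in schedule.presentations) + schedule.isi_ms
    neuron_ids = network.nodes["node_id"].to_numpy()
    spikes = {int(n): [] for n in neuron_ids}
    if noise_rate_hz > 0:
        for n in neuron_ids:
            k = rng.poisson(noise_rate_hz / 1000.0 * duration_ms)
            spikes[int(n)].append(rng.uniform(0.0, duration_ms, size=k))
    for lab, onset in schedule.presentations:
        for g in by_pattern.get(lab, []):
            w0, w1 = g.window_ms
            for n in g.neurons:
                k = rng.poisson(g.rate_hz / 1000.0 * (w1 - w0))
                spikes[int(n)].append(onset + rng.uniform(w0, w1, size=k))
    out = SpikeTrains()
    for n, chunks in spikes.items():
        t = np.sort(np.concatenate(chunks)) if chunks else np.empty(0)
        out[n] = np.unique(t)
    return out, list(assembly_plan)


# ---------------------------------------------------------------------------
# initial synaptic states
# ---------------------------------------------------------------------------

def init_synapse_states(
    syn_table: pd.DataFrame,
    pathway_p_potentiated,
    layer_of: Mapping[int, int],
    endpoints=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli bimodal initialisation: every synapse at rho = 0 or rho = 1.

    ``pathway_p_potentiated`` maps (pre_layer, post_layer) to the potentiated
    probability (a scalar applies to all pathways).  U_SE and g_AMPA_hat are
    set to the corresponding endpoint values of the low-pass conversion
    dynamics, g_NMDA_hat proportionally.
    """
    from .plasticity import PathwayEndpoints  # local import to avoid a cycle

    ep = endpoints or PathwayEndpoints()
    rng = np.random.default_rng(seed)
    df = syn_table.copy()
    if np.isscalar(pathway_p_potentiated):
        p = np.full(len(df), float(pathway_p_potentiated))
    else:
        p = np.array(
            [
                float(pathway_p_potentiated[(layer_of[int(a)], layer_of[int(b)])])
                for a, b in zip(df["pre"], df["post"])
            ]
        )
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pathway_p_potentiated outside [0, 1]")
    pot = rng.uniform(size=len(df)) < p
    df["rho"] = pot.astype(float)
    df["U_SE"] = np.where(pot, ep.u_se_p, ep.u_se_d) * ep.u_se_scale
    df["g_AMPA_hat"] = np.where(pot, ep.g_ampa_p, ep.g_ampa_d)
    df["g_NMDA_hat"] = np.where(pot, ep.g_nmda_p, ep.g_nmda_d)
    return df
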