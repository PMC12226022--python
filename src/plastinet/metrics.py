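"""Network-function metrics around plasticity.

Change summaries (depressed/potentiated/unchanged fractions, crossings of the
unstable fixed point rho* = 0.5, L2 change time series live in ``controls``),
spike-time reliability (mean cosine similarity of Gaussian-smoothed,
mean-centred trains over repetition pairs), pairwise spike-count correlations,
and input-output distance analyses: earth mover's distance between stimulus
patterns' fiber-location clouds against Euclidean/Hamming/EMD distances between
the resulting mean-efficacy vectors, correlated with a Mantel-style
permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linprog
from scipy.spatial.distance import cdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeSummary",
    "change_summary",
    "pairwise_correlations",
    "spike_time_reliability",
    "emd_point_clouds",
    "input_distance_matrix",
    "output_distance_matrix",
    "distance_correlation",
    "isi_histogram",
]


@dataclass
class ChangeSummary:
    synapse_table: pd.DataFrame      # per-synapse outcome, delta, crossing info
    connection_table: pd.DataFrame   # per-connection (mean rho) outcome
    fractions_synapse: pd.Series
    fractions_connection: pd.Series
    by_layer: pd.DataFrame
    by_neurite: pd.DataFrame
    crossing_times_up: np.ndarray    # first upward rho* crossings, s
    crossing_times_down: np.ndarray
    delta_g_moments: dict


def _first_crossings(rho: np.ndarray, times_s: np.ndarray, rho_star: float = 0.5):
    """First crossing of rho* per synapse: (+1 up / -1 down / 0 none, time)."""
    above = rho > rho_star
    direction = np.zeros(rho.shape[0], dtype=int)
    t_cross = np.full(rho.shape[0], np.nan)
    changed = above[:, 1:] != above[:, :-1]
    for i in range(rho.shape[0]):
        idx = np.nonzero(changed[i])[0]
        if idx.size:
            j = idx[0] + 1
            direction[i] = 1 if above[i, j] else -1
            t_cross[i] = times_s[j]
    return direction, t_cross


def change_summary(trace, syn_table: pd.DataFrame, tolerance: float = 1e-3,
                   rho_star: float = 0.5) -> ChangeSummary:
    """Classify plastic outcomes at synapse and connection level.

    Outcome is the sign of (last - first) rho beyond ``tolerance``; the first
    crossing of the unstable fixed point rho* is reported per synapse with its
    direction.  Aggregations by postsynaptic layer and neurite kind are taken
    from the synapse table when available.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    rho = np.asarray(trace.rho, float)
    if rho.shape[1] < 2:
        raise ValueError("trace needs at least 2 report times")
    times = np.asarray(trace.report_times_s, float)
    delta = rho[:, -1] - rho[:, 0]
    outcome = np.where(delta > tolerance, "potentiated",
                       np.where(delta < -tolerance, "depressed", "unchanged")).astype(object)
    direction, t_cross = _first_crossings(rho, times, rho_star)

    st = syn_table.set_index("syn_id").loc[trace.syn_ids].reset_index()
    per_syn = pd.DataFrame({
        "syn_id": trace.syn_ids, "pre": st["pre"], "post": st["post"],
        "delta_rho": delta, "outcome": outcome,
        "crossing": direction, "crossing_time_s": t_cross,
    })
    if "neurite_kind" in st:
        per_syn["neurite_kind"] = st["neurite_kind"]

    frac_syn = per_syn["outcome"].value_counts(normalize=True).reindex(
        ["depressed", "potentiated", "unchanged"], fill_value=0.0)

    conn_rho0 = per_syn.assign(r0=rho[:, 0], r1=rho[:, -1]).groupby(["pre", "post"])
    conn = conn_rho0[["r0", "r1"]].mean()
    cdelta = conn["r1"] - conn["r0"]
    conn["delta_rho"] = cdelta
    conn["outcome"] = np.where(cdelta > tolerance, "potentiated",
                               np.where(cdelta < -tolerance, "depressed", "unchanged"))
    frac_conn = conn["outcome"].value_counts(normalize=True).reindex(
        ["depressed", "potentiated", "unchanged"], fill_value=0.0)

    by_layer = pd.DataFrame()
    layer_map = None
    if "post_layer" in st:
        layer_map = st["post_layer"]
    if layer_map is not None:
        by_layer = pd.crosstab(layer_map, per_syn["outcome"], normalize="index")
    by_neurite = pd.DataFrame()
    if "neurite_kind" in per_syn:
        by_neurite = pd.crosstab(per_syn["neurite_kind"], per_syn["outcome"], normalize="index")

    dg = np.asarray(trace.g_ampa, float)
    dgd = dg[:, -1] - dg[:, 0]
    moments = {"mean": float(dgd.mean()), "std": float(dgd.std()),
               "skew": float(stats.skew(dgd)) if len(dgd) > 2 else np.nan}
    return ChangeSummary(
        synapse_table=per_syn,
        connection_table=conn.reset_index(),
        fractions_synapse=frac_syn,
        fractions_connection=frac_conn,
        by_layer=by_layer,
        by_neurite=by_neurite,
        crossing_times_up=np.sort(t_cross[direction == 1]),
        crossing_times_down=np.sort(t_cross[direction == -1]),
        delta_g_moments=moments,
    )


def pairwise_correlations(counts: np.ndarray, neuron_ids, pairs,
                          session_of=None) -> pd.DataFrame:
    """Pearson correlation of binned spike counts for requested neuron pairs.

    Zero-variance series are excluded (logged, r = NaN).  If ``session_of``
    maps neurons to sessions, counts are z-scored within each session before
    pooling.
    """
    counts = np.asarray(counts, float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 bins")
    ids = list(neuron_ids)
    pos = {int(n): i for i, n in enumerate(ids)}
    x = counts.copy()
    if session_of is not None:
        sessions = np.asarray([session_of[int(n)] for n in ids])
        for s in np.unique(sessions):
            sel = sessions == s
            mu = x[sel].mean()
            sd = x[sel].std()
            x[sel] = (x[sel] - mu) / (sd if sd > 0 else 1.0)
    rows = []
    for a, b in pairs:
        if int(a) not in pos or int(b) not in pos:
            raise ValueError(f"pair ({a}, {b}) references an unknown neuron")
        xa, xb = x[pos[int(a)]], x[pos[int(b)]]
        if xa.std() == 0 or xb.std() == 0:
            logger.info("zero-variance series in pair (%s, %s); r set to NaN", a, b)
            rows.append((int(a), int(b), np.nan))
            continue
        rows.append((int(a), int(b), float(np.corrcoef(xa, xb)[0, 1])))
    return pd.DataFrame(rows, columns=["a", "b", "r"])


def spike_time_reliability(spikes_by_repetition, window_ms: float,
                           sigma_ms: float = 10.0, bin_ms: float = 1.0) -> float:
    """Mean cosine similarity of smoothed, mean-centred spike trains over all
    repetition pairs.

    Each repetition is binned at 1 ms, convolved with a Gaussian kernel
    (sigma = 10 ms default) and mean-centred; pairs involving an empty
    repetition contribute 0 (logged).
    """
    reps = [np.asarray(r, float) for r in spikes_by_repetition]
    if len(reps) < 2:
        raise ValueError("need at least 2 repetitions")
    if all(len(r) == 0 for r in reps):
        raise ValueError("all repetitions are empty")
    n_bins = int(np.ceil(window_ms / bin_ms))
    smoothed = []
    for r in reps:
        h = np.zeros(n_bins)
        if len(r):
            idx = (r / bin_ms).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(h, idx, 1.0)
        s = gaussian_filter1d(h, sigma=sigma_ms / bin_ms, mode="constant")
        smoothed.append(s - s.mean())
    sims = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = smoothed[i], smoothed[j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                logger.info("empty repetition in pair (%d, %d): contributes 0", i, j)
                sims.append(0.0)
            else:
                sims.append(float(a @ b / (na * nb)))
    return float(np.mean(sims))


def emd_point_clouds(x: np.ndarray, y: np.ndarray, exact_max: int = 500,
                     sinkhorn_reg: float = 0.05, sinkhorn_iters: int = 2000) -> float:
    """Earth mover's distance between two point clouds with uniform weights.

    Exact optimal transport (linear program, HiGHS) up to ``exact_max`` points
    per cloud; entropic (Sinkhorn) approximation above, logged.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty point cloud")
    n, m = len(x), len(y)
    cost = cdist(x, y)
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    if max(n, m) <= exact_max:
        # LP over the transport polytope: row sums a, column sums b
        a_eq = []
        for i in range(n):
            row = np.zeros(n * m)
            row[i * m:(i + 1) * m] = 1.0
            a_eq.append(row)
        for j in range(m):
            col = np.zeros(n * m)
            col[j::m] = 1.0
            a_eq.append(col)
        res = linprog(cost.ravel(), A_eq=np.asarray(a_eq)[:-1], b_eq=np.concatenate([a, b])[:-1],
                      bounds=(0, None), method="highs")
        if not res.success:
            raise RuntimeError(f"transport LP failed: {res.message}")
        return float(res.fun)
    logger.info("clouds of %d/%d points: using entropic (Sinkhorn) approximation", n, m)
    k = np.exp(-cost / (sinkhorn_reg * cost.max()))
    u = np.ones(n) / n
    for _ in range(sinkhorn_iters):
        v = b / (k.T @ u)
        u = a / (k @ v)
    plan = u[:, None] * k * v[None, :]
    return float((plan * cost).sum())


def input_distance_matrix(fiber_locations: np.ndarray, patterns: dict,
                          labels=None) -> tuple[list, np.ndarray, np.ndarray]:
    """Pairwise input distances between stimulus patterns.

    EMD between the patterns' fiber-location point clouds (uniform weights,
    Euclidean ground metric) and the Hamming distance between their
    fiber-membership indicator vectors.  Returns (labels, emd, hamming).
    """
    labels = list(labels) if labels is not None else sorted(patterns)
    if len(labels) < 2:
        raise ValueError("need at least 2 patterns")
    locs = np.asarray(fiber_locations, float)
    n_fib = len(locs)
    emd = np.zeros((len(labels), len(labels)))
    ham = np.zeros_like(emd)
    ind = {}
    for lab in labels:
        fibers = sorted(patterns[lab])
        if not fibers:
            raise ValueError(f"pattern {lab} is empty")
        v = np.zeros(n_fib, dtype=bool)
        v[fibers] = True
        ind[lab] = v
    for i, la in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lb = labels[j]
            emd[i, j] = emd[j, i] = emd_point_clouds(locs[ind[la]], locs[ind[lb]])
            ham[i, j] = ham[j, i] = float(np.mean(ind[la] != ind[lb]))
    return labels, emd, ham


def output_distance_matrix(mean_rho_by_condition: pd.DataFrame, metric: str = "euclidean",
                           tolerance: float = 1e-3, initial=None) -> np.ndarray:
    """Pairwise distances between conditions' mean-efficacy vectors.

    Rows are conditions, columns a shared connection index.  Metrics:
    euclidean (L2 over connections); hamming (fraction of connections whose
    changed/unchanged flags differ, flags taken against ``initial`` when given,
    else against the other condition directly); emd (1-D EMD between the two
    value distributions).
    """
    m = mean_rho_by_condition
    if m.isna().any().any():
        raise ValueError("conditions must share a complete common connection index")
    x = m.to_numpy(float)
    n = len(x)
    flags = None
    if metric == "hamming" and initial is not None:
        init = np.asarray(initial, float)
        flags = np.abs(x - init[None, :]) > tolerance
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "euclidean":
                d = float(np.linalg.norm(x[i] - x[j]))
            elif metric == "hamming":
                if flags is not None:
                    d = float(np.mean(flags[i] != flags[j]))
                else:
                    d = float(np.mean(np.abs(x[i] - x[j]) > tolerance))
            elif metric == "emd":
                d = float(stats.wasserstein_distance(x[i], x[j]))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = d
    return out


def distance_correlation(input_d: np.ndarray, output_d: np.ndarray,
                         n_perm: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Pearson correlation of two condition-distance matrices with a
    Mantel-style permutation p-value (one-sided, positive association).

    Returns (r, p); r is NaN for a degenerate (constant) matrix.
    """
    din = np.asarray(input_d, float)
    dout = np.asarray(output_d, float)
    if din.shape != dout.shape or din.shape[0] != din.shape[1]:
        raise ValueError("distance matrices must be square and matching")
    n = din.shape[0]
    if n < 3:
        raise ValueError("need at least 3 conditions")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    a = squareform(din, checks=False)
    b = squareform(dout, checks=False)
    if a.std() == 0 or b.std() == 0:
        logger.info("degenerate distance matrix: correlation undefined")
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = squareform(dout[np.ix_(perm, perm)], checks=False)
        if np.corrcoef(a, bp)[0, 1] >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


def isi_histogram(spike_times, bins=None) -> tuple[np.ndarray, np.ndarray]:
    """Descriptive inter-spike-interval histogram (counts, bin edges)."""
    t = np.asarray(spike_times, float)
    isi = np.diff(t)
    if bins is None:
        bins = np.linspace(0, max(isi.max(), 1.0) if isi.size else 1.0, 51)
    counts, edges = np.histogram(isi, bins=bins)
    return counts, edges
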