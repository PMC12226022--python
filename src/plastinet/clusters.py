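"""Spatial synapse clusters on dendrites and change-likelihood statistics.

A synapse seeds a cluster when at least nine other synapses on the same
dendritic branch lie within 10 µm along-branch distance; qualifying synapses
within 10 µm of each other are merged transitively, so clusters of more than 10
synapses spanning more than 20 µm are possible.  Cluster significance is tested
against a Poisson placement model with exponentially distributed inter-synapse
distances, rate-fitted on all same-branch nearest-neighbour distances of the
neuron.  Target neurons for the cluster analyses are selected by jointly
maximising assembly-indegree and a synaptic clustering coefficient (SCC).  The
likelihood of plastic outcomes per synapse category is quantified with the
Michelson contrast (P(outcome|category) - P(outcome)) / (P(outcome|category) +
P(outcome)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SynapseCluster",
    "detect_clusters",
    "detect_clusters_brute",
    "cluster_significance",
    "synaptic_clustering_coefficient",
    "select_target_neurons",
    "michelson_contrast",
    "amplitude_by_category",
    "classify_outcomes",
]


@dataclass
class SynapseCluster:
    post_neuron: int
    branch_id: int
    member_syn_ids: tuple
    span_um: float
    presyn_category: str = "unspecified"

    @property
    def size(self) -> int:
        return len(self.member_syn_ids)


def _clusters_on_branch(syn_ids: np.ndarray, offsets: np.ndarray,
                        radius_um: float, min_size: int):
    """Seed-and-merge rule on one branch; returns lists of member indices."""
    order = np.argsort(offsets, kind="stable")
    x = offsets[order]
    ids = syn_ids[order]
    n = len(x)
    # seed rule: >= (min_size - 1) OTHER synapses within radius
    within = np.array([np.sum(np.abs(x - x[i]) <= radius_um) - 1 for i in range(n)])
    qualifies = within >= (min_size - 1)
    clusters = []
    current: list = []
    last_x = None
    for i in range(n):
        if not qualifies[i]:
            continue
        if last_x is not None and x[i] - last_x > radius_um:
            clusters.append(current)
            current = []
        current.append(i)
        last_x = x[i]
    if current:
        clusters.append(current)
    out = []
    for c in clusters:
        if len(c) >= min_size:
            out.append((ids[c], float(x[c].max() - x[c].min())))
    return out


def detect_clusters(syn_table: pd.DataFrame, neuron: int, radius_um: float = 10.0,
                    min_size: int = 10) -> list:
    """Detect synapse clusters on one postsynaptic neuron's branches."""
    df = syn_table[syn_table["post"] == neuron]
    if df.empty or df["path_offset"].isna().any():
        raise ValueError("neuron has no synapses with branch/offset geometry")
    clusters = []
    for branch, grp in df.groupby("branch_id"):
        found = _clusters_on_branch(grp["syn_id"].to_numpy(), grp["path_offset"].to_numpy(float),
                                    radius_um, min_size)
        for ids, span in found:
            clusters.append(SynapseCluster(post_neuron=int(neuron), branch_id=int(branch),
                                           member_syn_ids=tuple(int(i) for i in ids),
                                           span_um=span))
    return clusters


def detect_clusters_brute(syn_table: pd.DataFrame, neuron: int, radius_um: float = 10.0,
                          min_size: int = 10) -> list:
    """O(n^2) oracle: explicit qualify test plus transitive-closure merging."""
    df = syn_table[syn_table["post"] == neuron]
    clusters = []
    for branch, grp in df.groupby("branch_id"):
        ids = grp["syn_id"].to_numpy()
        x = grp["path_offset"].to_numpy(float)
        n = len(x)
        qual = [sum(1 for j in range(n) if j != i and abs(x[j] - x[i]) <= radius_um)
                >= min_size - 1 for i in range(n)]
        q_idx = [i for i in range(n) if qual[i]]
        # union-find over the <= radius relation among qualifying synapses
        parent = {i: i for i in q_idx}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in q_idx:
            for b in q_idx:
                if a < b and abs(x[a] - x[b]) <= radius_um:
                    parent[find(a)] = find(b)
        groups: dict = {}
        for i in q_idx:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            if len(members) >= min_size:
                mm = np.array(members)
                clusters.append(SynapseCluster(
                    post_neuron=int(neuron), branch_id=int(branch),
                    member_syn_ids=tuple(int(i) for i in np.sort(ids[mm])),
                    span_um=float(x[mm].max() - x[mm].min())))
    return clusters


def _nn_distances(offsets: np.ndarray) -> np.ndarray:
    """Nearest-neighbour (consecutive sorted) distances along a branch."""
    x = np.sort(np.asarray(offsets, float))
    return np.diff(x)


def cluster_significance(cluster: SynapseCluster, neuron_syn_table: pd.DataFrame,
                         eps_um: float = 1e-9) -> float:
    """One-sided p-value that the cluster is tighter than the Poisson null.

    The null assumes exponentially distributed inter-synapse distances with a
    rate fitted to all same-branch nearest-neighbour distances of the neuron;
    under it the sum of the cluster's n nearest-neighbour distances is
    Gamma(n, 1/lambda), and p is the lower-tail probability of the observed sum.
    """
    df = neuron_syn_table[neuron_syn_table["post"] == cluster.post_neuron]
    all_nn = np.concatenate([
        _nn_distances(grp["path_offset"].to_numpy(float))
        for _, grp in df.groupby("branch_id") if len(grp) >= 2
    ]) if len(df) else np.empty(0)
    if len(all_nn) < 2:
        raise ValueError("neuron needs at least 2 same-branch neighbour distances")
    zero = all_nn <= 0
    if np.any(zero):
        logger.info("jittering %d zero inter-synapse distances", int(zero.sum()))
        all_nn = np.where(zero, eps_um, all_nn)
    lam = 1.0 / all_nn.mean()
    members = df[df["syn_id"].isin(cluster.member_syn_ids)]
    d = _nn_distances(members["path_offset"].to_numpy(float))
    d = np.where(d <= 0, eps_um, d)
    return float(stats.gamma.cdf(d.sum(), a=len(d), scale=1.0 / lam))


def synaptic_clustering_coefficient(syn_table: pd.DataFrame, neuron: int,
                                    assembly_presyn, n_controls: int = 1000,
                                    seed: int = 0) -> float:
    """Synaptic clustering coefficient (SCC) of assembly synapses on a neuron.

    Z-score, against random same-size synapse subsets of the same neuron, of
    the mean same-branch nearest-neighbour distance among the neuron's
    assembly synapses, sign-flipped so that larger values mean more clustered.
    """
    df = syn_table[syn_table["post"] == neuron]
    assembly_presyn = set(int(a) for a in assembly_presyn)
    is_asm = df["pre"].isin(assembly_presyn).to_numpy()
    n_asm = int(is_asm.sum())
    if n_asm < 2 or n_asm == len(df):
        return 0.0

    def mean_nn(sel: np.ndarray) -> float:
        vals = []
        for _, grp in df[sel].groupby("branch_id"):
            if len(grp) >= 2:
                vals.append(_nn_distances(grp["path_offset"].to_numpy(float)))
        if not vals:
            return np.nan
        return float(np.concatenate(vals).mean())

    obs = mean_nn(is_asm)
    rng = np.random.default_rng(seed)
    null = np.empty(n_controls)
    idx = np.arange(len(df))
    for c in range(n_controls):
        sel = np.zeros(len(df), dtype=bool)
        sel[rng.choice(idx, size=n_asm, replace=False)] = True
        null[c] = mean_nn(sel)
    mu, sd = np.nanmean(null), np.nanstd(null)
    if not np.isfinite(obs) or sd == 0 or not np.isfinite(sd):
        return 0.0
    return float(-(obs - mu) / sd)


def select_target_neurons(assembly, syn_table: pd.DataFrame, network, n_select: int = 10,
                          n_controls: int = 200, seed: int = 0,
                          candidates=None) -> list:
    """Neurons maximising assembly-indegree and synaptic clustering coefficient.

    Assembly-indegree counts distinct presynaptic assembly members connected to
    the neuron; candidates are ranked by the product of their (descending)
    ranks in the two features and the top ``n_select`` returned.
    """
    assembly = set(int(a) for a in assembly)
    if not assembly:
        raise ValueError("assembly is empty")
    efferent = syn_table[syn_table["pre"].isin(assembly)]
    if efferent.empty:
        raise ValueError("assembly has no efferent synapses")
    if candidates is None:
        candidates = sorted(efferent["post"].unique().tolist())
    rows = []
    for c in candidates:
        onto = syn_table[syn_table["post"] == c]
        indeg = onto[onto["pre"].isin(assembly)]["pre"].nunique()
        scc = synaptic_clustering_coefficient(syn_table, c, assembly,
                                              n_controls=n_controls, seed=seed)
        rows.append((int(c), indeg, scc))
    df = pd.DataFrame(rows, columns=["neuron", "assembly_indegree", "scc"])
    # rank 1 = best; rank product, ties broken by indegree then id for determinism
    df["r_in"] = df["assembly_indegree"].rank(ascending=False, method="min")
    df["r_scc"] = df["scc"].rank(ascending=False, method="min")
    df["rank_product"] = df["r_in"] * df["r_scc"]
    df = df.sort_values(["rank_product", "r_in", "neuron"]).reset_index(drop=True)
    return df["neuron"].head(n_select).tolist()


def classify_outcomes(delta_rho, tolerance: float = 1e-3) -> np.ndarray:
    """Map per-synapse rho changes to {'potentiated','depressed','unchanged'}."""
    d = np.asarray(delta_rho, dtype=float)
    out = np.where(d > tolerance, "potentiated",
                   np.where(d < -tolerance, "depressed", "unchanged"))
    return out.astype(object)


def michelson_contrast(categories, outcomes, outcome_value) -> pd.Series:
    """Michelson contrast of an outcome per category.

    contrast = (P(outcome|category) - P(outcome)) / (P(outcome|category) +
    P(outcome)); bounded in [-1, 1], defined as 0 when both probabilities are
    zero.  Categories with no observations are reported as NaN (missing).
    """
    cat = pd.Series(list(categories), dtype=object)
    hit = pd.Series([o == outcome_value for o in outcomes], dtype=float)
    if len(cat) != len(hit):
        raise ValueError("categories and outcomes must align")
    p_overall = hit.mean()
    out = {}
    for c in pd.unique(cat):
        sel = cat == c
        if sel.sum() == 0:
            out[c] = np.nan
            continue
        p_cat = hit[sel].mean()
        if p_cat == 0 and p_overall == 0:
            out[c] = 0.0
        else:
            out[c] = (p_cat - p_overall) / (p_cat + p_overall)
    return pd.Series(out, name=f"contrast[{outcome_value}]")


def amplitude_by_category(delta_rho, assembly_flag, clustered_flag):
    """Mean |change| per (assembly x clustered) cell and a two-way ANOVA.

    Returns (cell_means DataFrame, anova_table DataFrame).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "delta": np.asarray(delta_rho, float),
        "assembly": np.where(np.asarray(assembly_flag, bool), "assembly", "non_assembly"),
        "clustered": np.where(np.asarray(clustered_flag, bool), "clustered", "non_clustered"),
    })
    sizes = df.groupby(["assembly", "clustered"]).size()
    if (sizes < 2).any() or len(sizes) < 4:
        raise ValueError("need >= 2 observations in every (assembly x clustered) cell")
    cell_means = df.groupby(["assembly", "clustered"])["delta"].mean().unstack()
    model = ols("delta ~ C(assembly) * C(clustered)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return cell_means, anova
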