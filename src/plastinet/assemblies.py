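"""Functional cell-assembly detection from spike trains.

Pipeline: (1) bin spikes into 20 ms bins; (2) find time bins whose population
rate exceeds the mean rate plus the 95th percentile of the standard deviations
of circularly shuffled controls; (3) build the cosine-similarity matrix of the
significant bins' activation vectors and cluster it hierarchically with Ward's
linkage, choosing the cluster number (scanned over 5..20) with the lowest
Davies-Bouldin index; (4) associate neurons with clusters by spike-train /
cluster-activation correlation against circular-shift controls, and accept a
cluster as an assembly if its members' mean pairwise correlation exceeds the
dataset-wide mean; (5) read out per-presentation assembly sequences and score
their reliability with the Hamming similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import kruskal
from sklearn.metrics import davies_bouldin_score

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedActivity",
    "AssemblyResult",
    "bin_spikes",
    "significant_bins",
    "cluster_significant_bins",
    "assign_neurons",
    "assembly_sequences",
    "jaccard_similarity",
    "hamming_similarity",
    "hamming_reliability",
    "detect_assemblies",
]


@dataclass
class BinnedActivity:
    bin_edges: np.ndarray   # (B+1,) ms
    counts: np.ndarray      # (N, B) int
    neuron_ids: np.ndarray  # (N,)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class AssemblyResult:
    significant_mask: np.ndarray          # (B,) bool
    labels: np.ndarray                    # label per significant bin
    n_clusters: int
    assemblies: dict                      # label -> frozenset of neuron ids
    db_index_by_k: dict                   # k -> Davies-Bouldin score
    threshold: float = np.nan
    rejected_clusters: tuple = ()

    def bin_labels(self) -> np.ndarray:
        """Label per bin over the whole recording; -1 where not significant."""
        out = np.full(self.significant_mask.shape, -1, dtype=int)
        out[np.nonzero(self.significant_mask)[0]] = self.labels
        return out


def bin_spikes(spikes, bin_ms: float = 20.0, t_start: float = 0.0,
               t_end: float | None = None, neuron_ids=None) -> BinnedActivity:
    """Bin per-neuron spike times into right-open [t, t+bin) count bins."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    if neuron_ids is None:
        neuron_ids = sorted(spikes.keys())
    neuron_ids = np.asarray(list(neuron_ids))
    if t_end is None:
        t_end = max((t[-1] for t in spikes.values() if len(t)), default=t_start) + bin_ms
    n_bins = int(np.ceil((t_end - t_start) / bin_ms))
    edges = t_start + bin_ms * np.arange(n_bins + 1)
    counts = np.zeros((len(neuron_ids), n_bins), dtype=np.int64)
    for i, n in enumerate(neuron_ids):
        t = np.asarray(spikes.get(n, ()), dtype=float)
        t = t[(t >= t_start) & (t < edges[-1])]
        if t.size:
            counts[i] = np.bincount(((t - t_start) / bin_ms).astype(np.int64), minlength=n_bins)
    return BinnedActivity(bin_edges=edges, counts=counts, neuron_ids=neuron_ids)


def _circular_shifts(counts: np.ndarray, rng) -> np.ndarray:
    """Independently circularly shift each neuron's binned train."""
    n, b = counts.shape
    shifts = rng.integers(0, b, size=n)
    cols = (np.arange(b)[None, :] - shifts[:, None]) % b
    return counts[np.arange(n)[:, None], cols]


def significant_bins(binned: BinnedActivity, n_shuffles: int = 100,
                     seed: int = 0) -> tuple[np.ndarray, float, dict]:
    """Bins whose population rate exceeds mean rate + 95th percentile of the
    shuffled-control standard deviations.

    Each control circularly shifts every neuron's binned spike train by an
    independent uniform offset ("shifted by any amount"), preserving rates and
    ISI structure.  Returns (mask, threshold, components).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    pop = binned.counts.sum(axis=0).astype(float)
    if pop.sum() == 0:
        raise ValueError("no spikes in the binned activity")
    rng = np.random.default_rng(seed)
    stds = np.empty(n_shuffles)
    for s in range(n_shuffles):
        stds[s] = _circular_shifts(binned.counts, rng).sum(axis=0).std()
    threshold = pop.mean() + np.percentile(stds, 95)
    components = {"mean_rate": float(pop.mean()), "std_95pct": float(np.percentile(stds, 95))}
    return pop > threshold, float(threshold), components


def cluster_significant_bins(binned: BinnedActivity, mask: np.ndarray,
                             k_range=range(5, 21)) -> tuple[np.ndarray, dict, int]:
    """Ward-linkage clustering of significant-bin activation vectors.

    Distances are 1 - cosine similarity of the per-bin spike-count vectors; the
    cluster count is chosen as the argmin of the Davies-Bouldin index over
    ``k_range`` (ties toward smaller k).  Returns (labels, db_by_k, chosen_k);
    labels are 0-based and aligned with the significant bins in time order.
    """
    vecs = binned.counts[:, np.asarray(mask, bool)].T.astype(float)  # (n_sig, N)
    n_sig = len(vecs)
    ks = [k for k in k_range if k < n_sig]
    if not ks:
        raise ValueError(f"{n_sig} significant bins: fewer than every requested k")
    dist = pdist(vecs, metric="cosine")
    dist = np.nan_to_num(dist, nan=1.0)  # zero vectors have undefined angle
    z = linkage(dist, method="ward")
    db_by_k = {}
    labels_by_k = {}
    for k in ks:
        lab = fcluster(z, t=k, criterion="maxclust") - 1
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            db_by_k[k] = np.inf
        else:
            db_by_k[k] = float(davies_bouldin_score(vecs, lab))
    chosen = min(ks, key=lambda k: (db_by_k[k], k))
    return labels_by_k[chosen], db_by_k, chosen


def _pearson_vs_activation(counts: np.ndarray, activation: np.ndarray) -> np.ndarray:
    """Pearson r of every neuron's binned counts with an activation series."""
    x = counts.astype(float)
    y = activation.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    return r


def _shift_correlations(counts: np.ndarray, activation: np.ndarray,
                        shifts: np.ndarray) -> np.ndarray:
    """Pearson r of circularly shifted counts with the activation series, for
    every neuron x shift, via FFT circular cross-correlation."""
    x = counts.astype(float)
    y = activation.astype(float)
    n, b = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    # circ[s] = sum_t x[(t - s) % b] y[t] = IFFT(FFT(x)* conj? ) — use rfft
    fx = np.fft.rfft(xc, axis=1)
    fy = np.fft.rfft(yc)
    circ = np.fft.irfft(np.conj(fx) * fy[None, :], n=b, axis=1)  # (n, b) over shifts
    with np.errstate(invalid="ignore", divide="ignore"):
        r = circ / (sx[:, None] * sy)
    return r[:, shifts]


def assign_neurons(binned: BinnedActivity, labels: np.ndarray, mask: np.ndarray,
                   n_shuffles: int = 1000, seed: int = 0,
                   binary_activation: bool = True) -> tuple[dict, dict]:
    """Associate neurons with bin clusters and accept clusters as assemblies.

    A neuron joins a cluster if its correlation with the cluster's activation
    time series exceeds the 95th percentile of correlations obtained from
    circularly shifted controls of its own spike train.  A cluster is accepted
    as an assembly only if the mean pairwise correlation among its significant
    neurons exceeds the dataset-wide mean pairwise correlation.  Zero-variance
    neurons are excluded (logged).  Returns (assemblies, diagnostics).
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, bool)
    sig_idx = np.nonzero(mask)[0]
    counts = binned.counts.astype(float)
    n, b = counts.shape
    variances = counts.var(axis=1)
    ok = variances > 0
    if np.any(~ok):
        logger.info("excluding %d zero-variance neurons from assembly membership",
                    int((~ok).sum()))
    corr = np.corrcoef(counts[ok]) if ok.sum() >= 2 else np.zeros((0, 0))
    iu = np.triu_indices(len(corr), k=1)
    dataset_mean_corr = float(np.nanmean(corr[iu])) if len(corr) else 0.0

    shifts = rng.integers(0, b, size=n_shuffles)
    assemblies: dict = {}
    rejected = []
    diagnostics = {"dataset_mean_corr": dataset_mean_corr, "member_r": {}}
    ok_ids = binned.neuron_ids[ok]
    ok_pos = {int(nid): i for i, nid in enumerate(ok_ids)}
    for lab in np.unique(labels):
        activation = np.zeros(b)
        bins_of = sig_idx[labels == lab]
        if binary_activation:
            activation[bins_of] = 1.0
        else:
            activation[bins_of] = counts[:, bins_of].sum(axis=0)
        r_obs = _pearson_vs_activation(counts[ok], activation)
        r_null = _shift_correlations(counts[ok], activation, shifts)
        thr = np.nanpercentile(r_null, 95, axis=1)
        members = ok_ids[np.nan_to_num(r_obs) > thr]
        diagnostics["member_r"][int(lab)] = dict(zip(members.tolist(),
                                                     r_obs[np.nan_to_num(r_obs) > thr].tolist()))
        if len(members) >= 2:
            pos = [ok_pos[int(m)] for m in members]
            sub = corr[np.ix_(pos, pos)]
            mean_pair = float(np.nanmean(sub[np.triu_indices(len(pos), k=1)]))
        else:
            mean_pair = -np.inf
        if mean_pair > dataset_mean_corr:
            assemblies[int(lab)] = frozenset(int(m) for m in members)
        else:
            rejected.append(int(lab))
    diagnostics["rejected_clusters"] = tuple(rejected)
    return assemblies, diagnostics


def assembly_sequences(labels: np.ndarray, mask: np.ndarray, bin_edges: np.ndarray,
                       presentations, window_ms: float = 200.0) -> dict:
    """Per-presentation label sequences in [onset, onset + window).

    Returns {pattern_label: [sequence, ...]} where a sequence lists the bin
    cluster label (int) or None for non-significant bins.
    """
    mask = np.asarray(mask, bool)
    bin_ms = float(bin_edges[1] - bin_edges[0])
    t0 = float(bin_edges[0])
    full = np.full(mask.shape, -1, dtype=int)
    full[np.nonzero(mask)[0]] = labels
    n_bins_window = int(round(window_ms / bin_ms))
    out: dict = {}
    for pat, onset in presentations:
        b0 = int(np.floor((onset - t0) / bin_ms))
        if b0 < 0 or b0 + n_bins_window > len(mask):
            raise ValueError("presentation window overruns the recording")
        seq = [int(l) if l >= 0 else None for l in full[b0:b0 + n_bins_window]]
        out.setdefault(pat, []).append(seq)
    return out


def jaccard_similarity(set_a, set_b) -> float:
    """Intersection over union of two sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both sets empty")
    return len(a & b) / len(a | b)


def hamming_similarity(seq_a, seq_b) -> float:
    """Fraction of positions at which two equal-length sequences agree."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) == 0:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(seq_a, seq_b)) / len(seq_a)


def hamming_reliability(sequences_by_pattern: dict, test: bool = False):
    """Mean pairwise Hamming similarity over the repetitions of each pattern.

    With ``test=True`` also returns the Kruskal-Wallis statistic and p-value of
    the per-pair similarities across patterns.
    """
    rel = {}
    groups = []
    for pat, seqs in sequences_by_pattern.items():
        if len(seqs) < 2:
            raise ValueError(f"pattern {pat} has fewer than 2 repetitions")
        sims = [hamming_similarity(seqs[i], seqs[j])
                for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
        rel[pat] = float(np.mean(sims))
        groups.append(sims)
    if test:
        stat, p = kruskal(*groups) if len(groups) >= 2 else (np.nan, np.nan)
        return rel, float(stat), float(p)
    return rel


def detect_assemblies(spikes, bin_ms: float = 20.0, n_shuffles_bins: int = 100,
                      n_shuffles_neurons: int = 1000, k_range=range(5, 21),
                      seed: int = 0, t_start: float = 0.0, t_end: float | None = None,
                      neuron_ids=None) -> tuple[AssemblyResult, BinnedActivity]:
    """Full assembly-detection pipeline on raw spike trains."""
    binned = bin_spikes(spikes, bin_ms=bin_ms, t_start=t_start, t_end=t_end,
                        neuron_ids=neuron_ids)
    mask, threshold, _ = significant_bins(binned, n_shuffles=n_shuffles_bins, seed=seed)
    labels, db_by_k, k = cluster_significant_bins(binned, mask, k_range=k_range)
    assemblies, diag = assign_neurons(binned, labels, mask,
                                      n_shuffles=n_shuffles_neurons, seed=seed + 1)
    result = AssemblyResult(
        significant_mask=mask, labels=labels, n_clusters=k, assemblies=assemblies,
        db_index_by_k=db_by_k, threshold=threshold,
        rejected_clusters=diag["rejected_clusters"],
    )
    return result, binned
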