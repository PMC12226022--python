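import numpy as np
import pandas as pd
import pytest

from plastinet import plasticity as pl
from plastinet import synthetic as syn


@pytest.fixture(scope="session")
def default_params():
    return pl.PlasticityParams()


@pytest.fixture(scope="session")
def default_kernels():
    return pl.DriverKernels()


@pytest.fixture(scope="session")
def reference_synapse(default_params, default_kernels):
    """One basal reference synapse with measured calcium peaks and derived
    thresholds, starting fully depressed."""
    ref = pl._reference_table(kinds=("basal",))
    c_pre, c_post = pl.measure_c_pre_c_post(ref, default_kernels, default_params)
    td, tp = pl.derive_thresholds(c_pre, c_post, ["basal"], default_params)
    ref = ref.copy()
    ref["c_pre"], ref["c_post"] = c_pre, c_post
    ref["theta_d"], ref["theta_p"] = td, tp
    ref["rho"] = 0.0
    return ref


@pytest.fixture(scope="session")
def small_network():
    return syn.gen_network(60, conn_prob_fn=lambda a, b: 0.08, seed=11)


def make_planted_dataset(seed, n_neurons=150, group_size=30, n_groups=3,
                         n_repetitions=12, rate_hz=100.0, noise_rate_hz=2.0,
                         window_ms=60.0):
    """Planted co-firing dataset: one assembly per base pattern."""
    net = syn.gen_network(n_neurons, conn_prob_fn=lambda a, b: 0.05, seed=seed)
    sched = syn.gen_patterns(n_bundles=20, base_fraction=0.12, n_fibers=100, seed=seed)
    labels = list("ABC")[:n_groups]
    syn.build_presentations(sched, n_repetitions=n_repetitions, isi_ms=500.0,
                            seed=seed + 1, labels=labels)
    rng = np.random.default_rng(seed + 2)
    perm = rng.permutation(net.nodes["node_id"].to_numpy())
    groups = [tuple(int(x) for x in perm[i * group_size:(i + 1) * group_size])
              for i in range(n_groups)]
    plan = [syn.PlantedGroup(pattern=lab, neurons=g, window_ms=(0.0, window_ms),
                             rate_hz=rate_hz)
            for lab, g in zip(labels, groups)]
    spikes, _ = syn.gen_planted_activity(net, sched, plan,
                                         noise_rate_hz=noise_rate_hz, seed=seed + 3)
    return net, sched, groups, spikes


@pytest.fixture(scope="session")
def planted_dataset():
    return make_planted_dataset(seed=101)


def random_digraph(rng, n, p):
    return [(i, j) for i in range(n) for j in range(n) if i != j and rng.uniform() < p]
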