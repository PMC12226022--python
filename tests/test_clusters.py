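"""Dendritic synapse clusters, Poisson-null significance, target selection,
Michelson contrast and change-amplitude ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastinet import clusters as cl


def make_table(offsets_by_branch, post=0, pre_of=None):
    rows = []
    sid = 0
    for branch, offsets in offsets_by_branch.items():
        for off in offsets:
            rows.append(dict(syn_id=sid, pre=pre_of[sid] if pre_of else sid + 1000,
                             post=post, branch_id=branch, path_offset=float(off),
                             neurite_kind="basal"))
            sid += 1
    return pd.DataFrame(rows)


class TestDetectClusters:
    def test_ten_tight_synapses_form_one_cluster(self):
        df = make_table({0: np.arange(10) * 1.0})
        found = cl.detect_clusters(df, 0)
        assert len(found) == 1 and found[0].size == 10

    def test_nine_synapses_no_cluster(self):
        df = make_table({0: np.arange(9) * 1.0})
        assert cl.detect_clusters(df, 0) == []

    def test_chained_windows_merge_beyond_20um(self):
        # two tight 10-synapse stretches 12 µm apart chain into one merged
        # cluster spanning more than 20 µm
        offsets = np.concatenate([np.arange(10) * 1.0, 12.0 + np.arange(10) * 1.0])
        df = make_table({0: offsets})
        found = cl.detect_clusters(df, 0)
        assert len(found) == 1
        assert found[0].size == 20 and found[0].span_um == pytest.approx(21.0)

    def test_branches_are_independent(self):
        df = make_table({0: np.arange(6) * 1.0, 1: 50 + np.arange(6) * 1.0})
        assert cl.detect_clusters(df, 0) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = make_table({b: np.sort(rng.uniform(0, 120, rng.integers(5, 40)))
                         for b in range(4)})
        fast = cl.detect_clusters(df, 0)
        brute = cl.detect_clusters_brute(df, 0)
        key = lambda c: (c.branch_id, c.member_syn_ids)
        assert sorted(map(key, fast)) == sorted(map(key, brute))

    def test_invariance_to_relabeling_and_order(self):
        rng = np.random.default_rng(3)
        offs = np.sort(rng.uniform(0, 60, 25))
        df = make_table({5: offs})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(branch_id=77)
        a = cl.detect_clusters(df, 0)
        b = cl.detect_clusters(relabeled, 0)
        assert sorted(tuple(sorted(c.member_syn_ids)) for c in a) == \
               sorted(tuple(sorted(c.member_syn_ids)) for c in b)

    def test_missing_geometry_rejected(self):
        df = make_table({0: [1.0, 2.0]})
        df.loc[0, "path_offset"] = np.nan
        with pytest.raises(ValueError):
            cl.detect_clusters(df, 0)


class TestClusterSignificance:
    def _neuron_with_cluster(self, cluster_scale, seed=0, n_bg=400):
        rng = np.random.default_rng(seed)
        bg = np.cumsum(rng.exponential(5.0, size=n_bg))
        cluster_offsets = 500 + np.cumsum(rng.exponential(cluster_scale, size=11))
        df = make_table({0: bg, 1: cluster_offsets - cluster_offsets.min()})
        members = df[df.branch_id == 1]
        cluster = cl.SynapseCluster(0, 1, tuple(members.syn_id), 0.0)
        return df, cluster

    def test_tight_cluster_significant(self):
        df, cluster = self._neuron_with_cluster(cluster_scale=0.3)
        assert cl.cluster_significance(cluster, df) < 1e-6

    def test_spread_cluster_not_significant(self):
        df, cluster = self._neuron_with_cluster(cluster_scale=50.0)
        assert cl.cluster_significance(cluster, df) > 0.9

    def test_zero_distances_pvalue_tends_to_zero(self):
        df = make_table({0: np.cumsum(np.full(50, 4.0)), 1: np.full(12, 7.0)})
        members = df[df.branch_id == 1]
        cluster = cl.SynapseCluster(0, 1, tuple(members.syn_id), 0.0)
        assert cl.cluster_significance(cluster, df) < 1e-12

    def test_null_calibration_uniform(self):
        # clusters whose spacings are drawn from the neuron's own exponential
        # law must produce uniform p-values
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(400):
            spacings = rng.exponential(5.0, size=600)
            offsets = np.cumsum(spacings)
            df = make_table({0: offsets})
            start = int(rng.integers(0, 580))
            ids = df.syn_id.to_numpy()[start:start + 11]
            cluster = cl.SynapseCluster(0, 0, tuple(ids), 0.0)
            pvals.append(cl.cluster_significance(cluster, df))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_neuron_rejected(self):
        df = make_table({0: [1.0]})
        cluster = cl.SynapseCluster(0, 0, (0,), 0.0)
        with pytest.raises(ValueError):
            cl.cluster_significance(cluster, df)


class TestTargetSelection:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        assembly = list(range(100, 110))
        rows = []
        sid = 0
        for post in range(20):
            n_asm = post % 6  # varying assembly-indegree
            pres = assembly[:n_asm] + [500 + i for i in range(8 - n_asm)]
            for pre in pres:
                for _ in range(3):
                    rows.append(dict(syn_id=sid, pre=pre, post=post,
                                     branch_id=post * 10 + int(rng.integers(0, 3)),
                                     path_offset=float(rng.uniform(0, 100)),
                                     neurite_kind="basal"))
                    sid += 1
        return pd.DataFrame(rows), assembly

    def test_zero_indegree_never_selected(self):
        df, assembly = self._toy()
        picked = cl.select_target_neurons(assembly, df, None, n_select=10,
                                          n_controls=50, seed=0)
        zero_indeg = {p for p in range(20) if p % 6 == 0}
        assert not set(picked[:10]) & zero_indeg or len(picked) > 10

    def test_concentrated_synapses_rank_higher(self):
        assembly = [100, 101, 102, 103]
        rng = np.random.default_rng(11)
        rows = []
        sid = 0
        for post, concentrated in ((0, True), (1, False)):
            for i, pre in enumerate(assembly):
                for j in range(3):
                    if concentrated:  # all assembly synapses tight on one branch
                        branch, off = post * 10, float(3 * i + j)
                    else:             # spread over branches and offsets
                        branch = post * 10 + int(rng.integers(0, 5))
                        off = float(rng.uniform(0, 200))
                    rows.append(dict(syn_id=sid, pre=pre, post=post, branch_id=branch,
                                     path_offset=off, neurite_kind="basal"))
                    sid += 1
            for extra in range(24):  # identical non-assembly background layout
                rows.append(dict(syn_id=sid, pre=900 + extra, post=post,
                                 branch_id=post * 10 + extra % 5,
                                 path_offset=float(rng.uniform(0, 200)),
                                 neurite_kind="basal"))
                sid += 1
        df = pd.DataFrame(rows)
        picked = cl.select_target_neurons(assembly, df, None, n_select=1,
                                          n_controls=400, seed=1)
        assert picked == [0]

    def test_matches_brute_force_ranking(self):
        df, assembly = self._toy(seed=2)
        picked = cl.select_target_neurons(assembly, df, None, n_select=20,
                                          n_controls=100, seed=3)
        # brute force: recompute both features and the rank product directly
        feats = []
        for c in sorted(df[df.pre.isin(assembly)].post.unique()):
            onto = df[df.post == c]
            indeg = onto[onto.pre.isin(assembly)].pre.nunique()
            scc = cl.synaptic_clustering_coefficient(df, c, assembly,
                                                     n_controls=100, seed=3)
            feats.append((c, indeg, scc))
        f = pd.DataFrame(feats, columns=["neuron", "indeg", "scc"])
        f["rp"] = (f.indeg.rank(ascending=False, method="min")
                   * f.scc.rank(ascending=False, method="min"))
        brute = f.sort_values(["rp", "indeg", "neuron"],
                              ascending=[True, False, True]).neuron.tolist()
        # rank-product order must agree (ties can permute within equal scores)
        assert f.set_index("neuron").loc[picked, "rp"].tolist() == \
               f.set_index("neuron").loc[brute, "rp"].tolist()

    def test_empty_assembly_rejected(self):
        df, _ = self._toy()
        with pytest.raises(ValueError):
            cl.select_target_neurons([], df, None)


class TestMichelsonContrast:
    def test_equal_probabilities_give_zero(self):
        cats = ["a"] * 50 + ["b"] * 50
        outs = (["hit", "miss"] * 25) * 2
        contrast = cl.michelson_contrast(cats, outs, "hit")
        assert contrast["a"] == pytest.approx(0.0)
        assert contrast["b"] == pytest.approx(0.0)

    def test_lower_bound_minus_one(self):
        cats = ["a"] * 10 + ["b"] * 10
        outs = ["miss"] * 10 + ["hit"] * 10
        contrast = cl.michelson_contrast(cats, outs, "hit")
        assert contrast["a"] == -1.0

    def test_toy_table_hand_arithmetic(self):
        # 20 synapses: category a has 8 with 6 hits; category b has 12 with 2
        cats = ["a"] * 8 + ["b"] * 12
        outs = ["hit"] * 6 + ["miss"] * 2 + ["hit"] * 2 + ["miss"] * 10
        p = 8 / 20
        pa, pb = 6 / 8, 2 / 12
        contrast = cl.michelson_contrast(cats, outs, "hit")
        assert contrast["a"] == pytest.approx((pa - p) / (pa + p))
        assert contrast["b"] == pytest.approx((pb - p) / (pb + p))

    def test_contrasts_cannot_all_share_one_sign(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cats = rng.choice(list("abcd"), size=200)
            outs = rng.choice(["hit", "miss"], size=200, p=[0.3, 0.7])
            contrast = cl.michelson_contrast(cats, outs, "hit").dropna()
            nonzero = contrast[contrast.abs() > 1e-12]
            if len(nonzero):
                assert nonzero.min() < 0 < nonzero.max() or len(nonzero) == 0

    def test_bounded(self):
        rng = np.random.default_rng(1)
        cats = rng.choice(list("ab"), size=100)
        outs = rng.choice(["hit", "miss"], size=100)
        contrast = cl.michelson_contrast(cats, outs, "hit")
        assert ((contrast >= -1) & (contrast <= 1)).all()


class TestOutcomeClassification:
    def test_tolerance_thresholding(self):
        out = cl.classify_outcomes([0.5, -0.5, 1e-5, 2e-3, -2e-3])
        assert out.tolist() == ["potentiated", "depressed", "unchanged",
                                "potentiated", "depressed"]


class TestAmplitudeAnova:
    def _balanced(self, shift=0.0, seed=0, n=40):
        rng = np.random.default_rng(seed)
        delta, asm_flag, clu_flag = [], [], []
        for a in (0, 1):
            for c in (0, 1):
                x = rng.normal(0, 1, n)
                if a and c:
                    x = x + shift
                delta.extend(x)
                asm_flag.extend([a] * n)
                clu_flag.extend([c] * n)
        return np.array(delta), np.array(asm_flag, bool), np.array(clu_flag, bool)

    def test_identical_groups_not_significant(self):
        d, a, c = self._balanced(shift=0.0, seed=1)
        _, anova = cl.amplitude_by_category(d, a, c)
        assert (anova["PR(>F)"].dropna() > 0.01).all()

    def test_shifted_cell_detected(self):
        d, a, c = self._balanced(shift=2.0, seed=2, n=100)
        _, anova = cl.amplitude_by_category(d, a, c)
        assert anova.loc["C(assembly):C(clustered)", "PR(>F)"] < 1e-6

    def test_balanced_toy_matches_textbook_arithmetic(self):
        # 2x2 balanced design: compare main-effect F with the hand formula
        d, a, c = self._balanced(shift=1.0, seed=3, n=30)
        cell_means, anova = cl.amplitude_by_category(d, a, c)
        df_ = pd.DataFrame({"y": d, "A": a, "B": c})
        n = 30
        grand = df_.y.mean()
        mean_a = df_.groupby("A").y.mean()
        ss_a = 2 * n * ((mean_a - grand) ** 2).sum()
        ss_resid = sum(((g.y - g.y.mean()) ** 2).sum()
                       for _, g in df_.groupby(["A", "B"]))
        f_a = (ss_a / 1) / (ss_resid / (4 * n - 4))
        assert anova.loc["C(assembly)", "F"] == pytest.approx(f_a, rel=1e-9)

    def test_empty_cells_rejected(self):
        with pytest.raises(ValueError):
            cl.amplitude_by_category([1.0, 2.0], [True, True], [True, False])
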