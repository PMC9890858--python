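"""Standardization, PCA, clustering, size labels, transitions, tanglegram."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rootarch.classify import (
    ClusterLabels,
    assign_size_labels,
    cluster,
    linkage_to_newick,
    pca,
    tanglegram_export,
    transition_matrix,
    zscore,
)


def _frame(X, traits=None, genotypes=None):
    n, p = X.shape
    return pd.DataFrame(
        X,
        index=genotypes or [f"G{i:03d}" for i in range(n)],
        columns=traits or [f"t{j:02d}" for j in range(p)],
    )


def _blobs(rng, centers, n_per, spread=1.0, p=5):
    X, labels = [], []
    for k, c in enumerate(centers):
        X.append(rng.normal(loc=c, scale=spread, size=(n_per, p)))
        labels += [k] * n_per
    return np.vstack(X), np.array(labels)


class TestZscore:
    def test_column_123_standardizes_to_unit_steps(self):
        z = zscore(_frame(np.array([[1.0], [2.0], [3.0]])))
        assert np.allclose(z.values.to_numpy().ravel(), [-1, 0, 1])

    def test_columns_centered_and_scaled(self):
        rng = np.random.default_rng(0)
        z = zscore(_frame(rng.normal(2, 7, size=(40, 6))))
        assert np.abs(z.values.mean()).max() < 1e-12
        assert np.abs(z.values.std(ddof=1) - 1).max() < 1e-12

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="t01"):
            z = zscore(_frame(X))
        assert z.dropped == ("t01",)
        assert list(z.values.columns) == ["t00"]

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            zscore(_frame(np.ones((1, 3))))


class TestPca:
    def test_low_rank_data_concentrates_on_dim1(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(100, 1))
        v = rng.normal(size=(1, 8))
        z = zscore(_frame(u @ v + 1e-4 * rng.normal(size=(100, 8))))
        model = pca(z)
        assert model.var_pct[0] > 99.0
        assert model.var_pct.sum() == pytest.approx(100.0)

    def test_isotropic_data_spreads_variance(self):
        rng = np.random.default_rng(2)
        z = zscore(_frame(rng.normal(size=(500, 22))))
        model = pca(z)
        assert 100 / 22 * 0.9 < model.var_pct[0] < 9.0

    def test_negating_input_negates_scores_not_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        m1 = pca(zscore(_frame(X)))
        m2 = pca(zscore(_frame(-X)))
        assert np.allclose(m2.var_pct, m1.var_pct)
        assert np.allclose(m2.scores.to_numpy(), -m1.scores.to_numpy())

    def test_dim1_oriented_by_network_length(self):
        rng = np.random.default_rng(4)
        size = rng.normal(size=(80, 1))
        X = size @ np.array([[1.0, 1.0, -0.5]]) + 0.1 * rng.normal(size=(80, 3))
        z = zscore(_frame(X, traits=["NeL", "NeA", "NeS"]))
        model = pca(z)
        assert model.loadings.loc["NeL", "Dim1"] >= 0
        assert model.sign_anchor == "NeL"

    def test_missing_values_rejected(self):
        X = np.ones((5, 3)) + np.arange(5)[:, None]
        X[0, 0] = np.nan
        z = zscore(_frame(X))
        with pytest.raises(ValueError, match="missing"):
            pca(z)


class TestCluster:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(5)
        X, labels = _blobs(rng, centers=[0.0, 10.0, 20.0], n_per=20)
        cl = cluster(zscore(_frame(X)), k=3)
        assert adjusted_rand_score(labels, cl.cluster.to_numpy()) == 1.0

    def test_three_points_three_singletons(self):
        X = np.array([[0.0, 0], [5, 5], [9, 0]])
        cl = cluster(zscore(_frame(X)), k=3)
        assert sorted(cl.cluster.to_numpy()) == [1, 2, 3]

    def test_duplicated_rows_cluster_together(self):
        rng = np.random.default_rng(6)
        X, _ = _blobs(rng, centers=[0.0, 8.0, 16.0], n_per=6)
        XX = np.vstack([X, X])
        names = [f"G{i:03d}" for i in range(len(X))]
        cl = cluster(zscore(_frame(XX, genotypes=names + [n + "d" for n in names])),
                     k=3)
        lab = cl.cluster
        for n in names:
            assert lab[n] == lab[n + "d"]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k=5"):
            cluster(zscore(_frame(np.random.default_rng(0).normal(size=(3, 2)))),
                    k=5)

    def test_deterministic_labelling(self):
        rng = np.random.default_rng(7)
        z = zscore(_frame(rng.normal(size=(30, 4))))
        a = cluster(z, k=3)
        b = cluster(z, k=3)
        assert a.cluster.equals(b.cluster)


class TestSizeLabels:
    def _z_with_sizes(self, offsets, nel_tweak=None):
        rng = np.random.default_rng(8)
        traits = ["NeA", "NeL", "NeP", "NeSA", "NeV", "NeB"]
        rows = []
        for k, off in enumerate(offsets):
            for _ in range(10):
                rows.append(np.r_[np.full(5, off) + 0.01 * rng.normal(size=5),
                                  rng.normal()])
        X = np.array(rows)
        if nel_tweak is not None:
            for k, dv in enumerate(nel_tweak):
                X[k * 10:(k + 1) * 10, 1] += dv
        return zscore(_frame(X, traits=traits))

    def test_clusters_ranked_small_medium_large(self):
        z = self._z_with_sizes([-1.0, 0.0, 1.0])
        cl = cluster(z, k=3)
        labeled = assign_size_labels(cl, z)
        for gi, expect in [(0, "small"), (10, "medium"), (20, "large")]:
            assert labeled.size_label.iloc[gi] == expect

    def test_tie_broken_by_network_length(self):
        # two clusters with equal mean size score, one with larger NeL
        z = self._z_with_sizes([-1.0, 0.5, 0.5], nel_tweak=[0.0, -0.3, 0.3])
        cl = cluster(z, k=3)
        labeled = assign_size_labels(cl, z)
        means = {}
        for cid in sorted(cl.cluster.unique()):
            members = cl.cluster.index[cl.cluster == cid]
            means[cid] = z.values.loc[members, "NeL"].mean()
        large_cid = labeled.cluster[labeled.size_label == "large"].iloc[0]
        assert means[large_cid] == max(means.values())

    def test_requires_three_clusters(self):
        rng = np.random.default_rng(9)
        z = zscore(_frame(rng.normal(size=(10, 3))))
        cl = cluster(z, k=2)
        with pytest.raises(ValueError, match="3 clusters"):
            assign_size_labels(cl, z)


def _labels(mapping, linkage_matrix=None):
    genotypes = list(mapping)
    cl = pd.Series([1] * len(genotypes), index=genotypes, name="cluster")
    size = pd.Series([mapping[g] for g in genotypes], index=genotypes,
                     name="size_label")
    if linkage_matrix is None:
        from scipy.cluster import hierarchy
        rng = np.random.default_rng(0)
        linkage_matrix = hierarchy.linkage(rng.normal(size=(len(genotypes), 2)))
    return ClusterLabels(cluster=cl, linkage_matrix=linkage_matrix,
                         size_label=size)


class TestTransitions:
    def test_identical_labels_are_identity(self):
        m = {f"G{i}": lab for i, lab in
             enumerate(["small"] * 3 + ["medium"] * 4 + ["large"] * 3)}
        tr = transition_matrix(_labels(m), _labels(m))
        assert np.allclose(np.diag(tr.matrix_pct), 100.0)
        assert tr.same_pct == 100.0 and tr.two_step_pct == 0.0

    def test_small_to_large_is_two_step(self):
        hp = {f"G{i}": "small" for i in range(5)}
        lp = {f"G{i}": "large" for i in range(5)}
        tr = transition_matrix(_labels(hp), _labels(lp))
        assert tr.two_step_pct == 100.0
        assert tr.matrix_pct.loc["small", "large"] == 100.0

    def test_hand_built_ten_genotype_case(self):
        hp = dict(zip([f"G{i}" for i in range(10)],
                      ["small"] * 4 + ["medium"] * 4 + ["large"] * 2))
        lp = dict(zip([f"G{i}" for i in range(10)],
                      ["small", "small", "medium", "large",
                       "medium", "medium", "small", "large",
                       "large", "medium"]))
        tr = transition_matrix(_labels(hp), _labels(lp))
        # brute-force counts: small->{2 small,1 medium,1 large}, etc.
        assert tr.counts.loc["small", "small"] == 2
        assert tr.matrix_pct.loc["small", "small"] == pytest.approx(50.0)
        assert tr.matrix_pct.loc["small", "large"] == pytest.approx(25.0)
        assert tr.matrix_pct.loc["medium", "medium"] == pytest.approx(50.0)
        assert tr.matrix_pct.loc["large", "large"] == pytest.approx(50.0)
        same = (2 + 2 + 1) / 10 * 100
        assert tr.same_pct == pytest.approx(same)
        assert tr.same_pct + tr.one_step_pct + tr.two_step_pct == pytest.approx(100)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(10)
        cats = ["small", "medium", "large"]
        hp = {f"G{i}": cats[rng.integers(3)] for i in range(60)}
        lp = {f"G{i}": cats[rng.integers(3)] for i in range(60)}
        tr = transition_matrix(_labels(hp), _labels(lp))
        sums = tr.matrix_pct.sum(axis=1).dropna()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_mismatched_genotype_sets_rejected(self):
        hp = {f"G{i}": "small" for i in range(5)}
        lp = {f"G{i}": "small" for i in range(4)}
        with pytest.raises(ValueError, match="G4"):
            transition_matrix(_labels(hp), _labels(lp))


class TestTanglegram:
    def _clusterings(self, n=12, seed=11):
        rng = np.random.default_rng(seed)
        z_hp = zscore(_frame(rng.normal(size=(n, 4))))
        z_lp = zscore(_frame(rng.normal(size=(n, 4))))
        hp = assign_size_labels(cluster(z_hp, k=3), z_hp)
        lp = assign_size_labels(cluster(z_lp, k=3), z_lp)
        return z_hp, z_lp, hp, lp

    def test_newick_round_trips_through_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        _, _, hp, lp = self._clusterings()
        out = tanglegram_export(hp, lp)
        tree = Phylo.read(StringIO(out["hp_newick"]), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(hp.genotypes)

    def test_mapping_covers_every_genotype_once(self):
        _, _, hp, lp = self._clusterings()
        out = tanglegram_export(hp, lp)
        mapping = out["mapping"]
        assert sorted(mapping["genotype"]) == sorted(hp.genotypes)
        assert sorted(mapping["hp_leaf_order"]) == list(range(len(hp.genotypes)))
        assert sorted(mapping["lp_leaf_order"]) == list(range(len(hp.genotypes)))

    def test_serialization_invariant_to_row_order(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 4))
        names = [f"G{i:03d}" for i in range(10)]
        z1 = zscore(_frame(X, genotypes=names))
        perm = rng.permutation(10)
        z2 = zscore(_frame(X[perm], genotypes=[names[i] for i in perm]))
        nwk1 = linkage_to_newick(cluster(z1, k=3).linkage_matrix, z1.genotypes)
        nwk2 = linkage_to_newick(cluster(z2, k=3).linkage_matrix, z2.genotypes)
        assert nwk1 == nwk2

    def test_leaf_set_mismatch_rejected(self):
        _, _, hp, _ = self._clusterings(n=8)
        _, _, _, lp = self._clusterings(n=9, seed=13)
        with pytest.raises(ValueError, match="identical genotype sets"):
            tanglegram_export(hp, lp)
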