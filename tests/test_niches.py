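import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from nichescope.niches import (
    build_ko_presence,
    choose_k_elbow,
    classical_mds,
    fisher_enrichment,
    jaccard_distances,
    kmeans_assign,
    ko_set_overlaps,
    adjusted_prevalence,
    procrustes_protest,
)


def presence(rows: dict[str, set[str]]) -> pd.DataFrame:
    kos = sorted(set().union(*rows.values()))
    return pd.DataFrame(
        [[1 if k in s else 0 for k in kos] for s in rows.values()],
        index=list(rows), columns=kos,
    )


class TestBuildKoPresence:
    def test_multiple_genes_collapse_to_one(self, toy_annotations):
        m = build_ko_presence(toy_annotations)
        assert m.loc["A", "K1"] == 1 and m.loc["A", "K2"] == 1
        assert m.loc["B", "K2"] == 1 and m.loc["B", "K3"] == 1
        assert m.loc["A", "K3"] == 0

    def test_gene_without_ko_ignored(self, toy_annotations):
        m = build_ko_presence(toy_annotations)
        assert set(m.columns) == {"K1", "K2", "K3"}

    def test_columns_sorted(self, toy_annotations):
        m = build_ko_presence(toy_annotations)
        assert list(m.columns) == sorted(m.columns)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_ko_presence(pd.DataFrame(
                columns=["gene_id", "rmag_id", "ko_id", "foam_l1", "length_bp"]))


class TestJaccard:
    def test_half_overlap(self):
        m = presence({"a": {"K1", "K2", "K3"}, "b": {"K2", "K3", "K4"}})
        assert jaccard_distances(m).loc["a", "b"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        m = presence({"a": {"K1"}, "b": {"K1"}, "c": {"K2"}})
        d = jaccard_distances(m)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            x = rng.integers(0, 2, size=(rng.integers(2, 7), rng.integers(2, 10)))
            m = pd.DataFrame(x, index=[f"r{i}" for i in range(x.shape[0])],
                             columns=[f"K{j}" for j in range(x.shape[1])])
            d = jaccard_distances(m)
            for i, j in itertools.combinations(range(x.shape[0]), 2):
                a, b = set(np.where(x[i])[0]), set(np.where(x[j])[0])
                union = len(a | b)
                expected = 0.0 if union == 0 else 1 - len(a & b) / union
                assert d.iloc[i, j] == pytest.approx(expected)
                assert d.iloc[j, i] == pytest.approx(expected)

    def test_all_zero_pair_defined_zero(self):
        m = presence({"a": set(), "b": set(), "c": {"K1"}})
        m["K1"] = [0, 0, 1]
        d = jaccard_distances(m[["K1"]])
        assert d.loc["a", "b"] == 0.0


class TestClassicalMds:
    def test_collinear_spacing_preserved(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        emb, _ = classical_mds(d, dims=1)
        x = emb.values.ravel()
        assert abs(x[0] - x[1]) == pytest.approx(abs(x[1] - x[2]), abs=1e-9)

    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(15, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        emb, var = classical_mds(d, dims=2)
        from scipy.spatial import procrustes
        _, _, m2 = procrustes(pts, emb.values)
        assert m2 < 1e-10
        assert var.sum() == pytest.approx(1.0, abs=1e-8)

    def test_two_points_at_half(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        emb, _ = classical_mds(d, dims=1)
        assert sorted(emb.values.ravel()) == pytest.approx([-0.5, 0.5])

    def test_row_order_invariance(self, rng):
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        df = pd.DataFrame(d, index=[f"r{i}" for i in range(10)],
                          columns=[f"r{i}" for i in range(10)])
        perm = rng.permutation(10)
        ids = [f"r{i}" for i in perm]
        e1, _ = classical_mds(df)
        e2, _ = classical_mds(df.loc[ids, ids])
        # same inter-point distances in both embeddings
        from scipy.spatial.distance import pdist as pd2
        np.testing.assert_allclose(
            sorted(pd2(e1.loc[ids].values)), sorted(pd2(e2.values)), atol=1e-8
        )


class TestElbow:
    def test_hand_curve_selects_k2(self, monkeypatch):
        # curve 100, 20, 18, ..., 12 has its maximum chord distance at k=2
        curve = {1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0, 5: 16.0, 6: 15.0,
                 7: 14.0, 8: 13.0, 9: 12.0}
        import nichescope.niches as mod
        monkeypatch.setattr(
            mod, "_withinss", lambda x, k, seed, n_restarts=25: (curve[k], None)
        )
        emb = pd.DataFrame(np.zeros((20, 2)))
        k, got = choose_k_elbow(emb, seed=0)
        assert k == 2
        assert got == curve

    def test_identical_points_fall_back_to_kmin(self):
        emb = pd.DataFrame(np.ones((12, 2)))
        k, curve = choose_k_elbow(emb, seed=0)
        assert k == 1
        assert curve[1] == pytest.approx(0.0)

    def test_override(self):
        emb = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)))
        k, _ = choose_k_elbow(emb, seed=0, k_override=6)
        assert k == 6


class TestKmeans:
    def test_separated_pairs_grouped(self):
        emb = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]],
            index=["a", "b", "c", "d"], columns=["MDS1", "MDS2"],
        )
        a = kmeans_assign(emb, 2, seed=0)
        assert a.labels["a"] == a.labels["b"]
        assert a.labels["c"] == a.labels["d"]
        assert a.labels["a"] != a.labels["c"]

    def test_k1_single_label(self):
        emb = pd.DataFrame(np.random.default_rng(1).normal(size=(8, 2)))
        a = kmeans_assign(emb, 1, seed=0)
        assert set(a.labels) == {1}

    def test_k_equals_n(self):
        emb = pd.DataFrame(np.random.default_rng(2).normal(size=(5, 2)))
        a = kmeans_assign(emb, 5, seed=0)
        assert sorted(a.labels) == [1, 2, 3, 4, 5]

    def test_k_above_n_rejected(self):
        emb = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            kmeans_assign(emb, 4, seed=0)

    def test_labels_ordered_by_size(self):
        emb = pd.DataFrame(
            np.concatenate([np.zeros((8, 2)), 10 + np.zeros((3, 2))]),
        )
        a = kmeans_assign(emb, 2, seed=0)
        assert (a.labels.value_counts().loc[1] == 8)


class TestOverlaps:
    def test_two_set_partition(self):
        m = presence({"a": {"K1", "K2", "K3"}, "b": {"K2", "K3", "K4"}})
        labels = pd.Series({"a": 1, "b": 2})
        unions, regions = ko_set_overlaps(m, labels)
        assert unions == {1: 3, 2: 3}
        assert regions[frozenset({1})] == 1
        assert regions[frozenset({2})] == 1
        assert regions[frozenset({1, 2})] == 2

    def test_single_cluster(self):
        m = presence({"a": {"K1", "K2"}, "b": {"K2"}})
        labels = pd.Series({"a": 1, "b": 1})
        unions, regions = ko_set_overlaps(m, labels)
        assert regions == {frozenset({1}): 2}

    def test_region_counts_sum_to_global_union(self, rng):
        # brute-force set-arithmetic oracle on random matrices
        for _ in range(100):
            n, p = int(rng.integers(3, 9)), int(rng.integers(2, 12))
            x = rng.integers(0, 2, size=(n, p))
            m = pd.DataFrame(x, index=[f"r{i}" for i in range(n)],
                             columns=[f"K{j}" for j in range(p)])
            labels = pd.Series(rng.integers(1, 4, size=n), index=m.index)
            unions, regions = ko_set_overlaps(m, labels)
            global_union = set(m.columns[(x > 0).any(axis=0)])
            assert sum(regions.values()) == len(global_union)
            for s, cnt in regions.items():
                oracle = 0
                for ko in global_union:
                    member = frozenset(
                        c for c in labels.unique()
                        if m.loc[labels[labels == c].index, ko].any()
                    )
                    if member == s:
                        oracle += 1
                assert cnt == oracle


class TestFisher:
    def test_fully_concentrated_p_equals_inverse_binomial(self):
        # KO in all 10 members of a size-10 cluster and none of 30 others:
        # the hypergeometric tail collapses to 1 / C(40, 10)
        rows = {f"r{i}": ({"K1"} if i < 10 else {"K0"}) for i in range(40)}
        m = presence(rows)
        labels = pd.Series([1] * 10 + [2] * 30, index=m.index)
        res = fisher_enrichment(m, labels)
        hit = res.query("ko_id == 'K1' and cluster == 1")["p"].iloc[0]
        # oracle: exhaustive hypergeometric sum over the single attainable draw
        assert hit == pytest.approx(1 / comb(40, 10), rel=1e-10)

    def test_ubiquitous_ko_p_one(self):
        rows = {f"r{i}": {"K1", f"P{i}"} for i in range(8)}
        m = presence(rows)
        labels = pd.Series([1] * 4 + [2] * 4, index=m.index)
        res = fisher_enrichment(m, labels)
        np.testing.assert_allclose(res.query("ko_id == 'K1'")["p"].values, 1.0)

    def test_absent_ko_p_one(self):
        m = presence({"a": {"K1"}, "b": {"K1"}, "c": {"K1"}, "d": {"K1"}})
        m["K9"] = 0
        labels = pd.Series([1, 1, 2, 2], index=m.index)
        res = fisher_enrichment(m, labels)
        np.testing.assert_allclose(res.query("ko_id == 'K9'")["p"].values, 1.0)

    def test_bh_adjustment_matches_stepup_oracle(self, rng):
        # independent step-up implementation of Benjamini–Hochberg
        def bh(pvals):
            p = np.asarray(pvals, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        assert bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        x = rng.integers(0, 2, size=(16, 10))
        m = pd.DataFrame(x, index=[f"r{i}" for i in range(16)],
                         columns=[f"K{j}" for j in range(10)])
        labels = pd.Series([1] * 8 + [2] * 8, index=m.index)
        res = fisher_enrichment(m, labels)
        expected = np.minimum(bh(res["p"].values), 1.0)
        # our surface additionally enforces p_adj >= p
        np.testing.assert_allclose(
            res["p_adj"].values, np.maximum(expected, res["p"].values), atol=1e-12
        )

    def test_p_adj_at_least_p(self, rng):
        x = rng.integers(0, 2, size=(20, 15))
        m = pd.DataFrame(x, index=[f"r{i}" for i in range(20)],
                         columns=[f"K{j}" for j in range(15)])
        labels = pd.Series(rng.integers(1, 3, size=20), index=m.index)
        res = fisher_enrichment(m, labels)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_null_fdr_controlled(self, rng):
        # 200 KOs independent of labels: empirical FDR ≤ alpha + 2 s.e.
        n = 40
        x = rng.integers(0, 2, size=(n, 200))
        m = pd.DataFrame(x, index=[f"r{i}" for i in range(n)],
                         columns=[f"K{j}" for j in range(200)])
        labels = pd.Series([1] * 20 + [2] * 20, index=m.index)
        res = fisher_enrichment(m, labels, alpha=0.05)
        n_false = int(res["enriched"].sum())
        n_called = max(n_false, 1)
        fdr = n_false / n_called if n_false else 0.0
        se = np.sqrt(0.05 * 0.95 / 200)
        assert fdr <= 0.05 + 2 * se or n_false == 0


class TestAdjustedPrevalence:
    def test_completeness_division(self):
        rows = {f"r{i}": ({"K1"} if i < 12 else {"K0"}) for i in range(24)}
        m = presence(rows)
        labels = pd.Series(1, index=m.index)
        comp = pd.Series(0.762, index=m.index)
        out = adjusted_prevalence(m, labels, comp, {"K1"})
        assert out[1] == pytest.approx(0.5 / 0.762)

    def test_capped_at_one(self):
        m = presence({"a": {"K1"}, "b": {"K1"}})
        labels = pd.Series(1, index=m.index)
        comp = pd.Series(0.5, index=m.index)
        assert adjusted_prevalence(m, labels, comp, {"K1"})[1] == 1.0

    def test_zero_prevalence(self):
        m = presence({"a": {"K1"}, "b": {"K1"}})
        labels = pd.Series(1, index=m.index)
        comp = pd.Series(1.0, index=m.index)
        assert adjusted_prevalence(m, labels, comp, {"K9"})[1] == 0.0


class TestProcrustes:
    def test_rotated_scaled_copy_m2_zero(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["MDS1", "MDS2"])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = pd.DataFrame(3.0 * x.values @ rot + 5.0, index=x.index,
                         columns=x.columns)
        m2, corr, p = procrustes_protest(x, y, n_perm=99, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        assert corr == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_p_lower_bound(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 2)))
        y = pd.DataFrame(x.values + rng.normal(scale=0.01, size=(30, 2)),
                         index=x.index)
        _, _, p = procrustes_protest(x, y, n_perm=199, seed=1)
        assert p >= 1 / 200

    def test_independent_configs_low_correlation(self, rng):
        corrs, ps = [], []
        for rep in range(20):
            x = pd.DataFrame(rng.normal(size=(60, 2)))
            y = pd.DataFrame(rng.normal(size=(60, 2)), index=x.index)
            m2, corr, p = procrustes_protest(x, y, n_perm=99, seed=rep)
            corrs.append(corr)
            ps.append(p)
        assert np.mean(corrs) < 0.4
        assert min(ps) > 0.001  # no systematically significant association

    def test_too_few_rows_rejected(self):
        x = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            procrustes_protest(x, x.copy(), n_perm=9)
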