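"""Rarefaction, Ward clustering, silhouette selection and cluster support."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phyllodyn.data_model import FeatureTable
from phyllodyn.succession import (
    SuccessionClustering,
    abundance_filter,
    cluster_timeseries,
    cut_tree,
    name_clusters,
    rarefy,
    scale_by_feature_total,
    silhouette_select_k,
    ward_cluster,
)

from conftest import random_table, simple_metadata


def ward_oracle_partitions(x):
    """Greedy Ward agglomeration straight from the minimum-variance
    objective: at each step merge the pair of clusters whose union minimises
    the increase in within-cluster sum of squares
    ΔSS = n_a n_b / (n_a + n_b) · ||centroid_a − centroid_b||².
    Centroids are recomputed from raw coordinates (no Lance-Williams
    recursion), making this an independent route. Returns the partition at
    every k as sets of frozensets.
    """
    clusters = [frozenset([i]) for i in range(len(x))]
    partitions = {len(clusters): set(clusters)}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = x[list(clusters[a])].mean(axis=0)
                cb = x[list(clusters[b])].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                delta = na * nb / (na + nb) * np.sum((ca - cb) ** 2)
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        partitions[len(clusters)] = set(clusters)
    return partitions


def _partition_from_labels(labels):
    out = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}


class TestRarefy:
    def test_columns_sum_to_depth(self, rng):
        t = random_table(rng, n_features=20, n_samples=6, lam=80)
        out = rarefy(t, depth=500, seed=1)
        assert (out.sample_sums() == 500).all()

    def test_sample_at_exact_depth_unchanged(self):
        col = np.array([100, 200, 612])
        t = FeatureTable(pd.DataFrame({"s1": col, "s2": col * 3},
                                      index=["a", "b", "c"]))
        out = rarefy(t, depth=912, seed=0)
        assert (out.counts["s1"].to_numpy() == col).all()

    def test_shallow_samples_dropped(self, rng):
        t = random_table(rng, n_features=10, n_samples=4, lam=5)
        t.counts["S0"] = 0
        t.counts.loc["F0", "S0"] = 3
        out = rarefy(t, depth=20, seed=0)
        assert "S0" not in out.sample_ids

    def test_no_sample_reaches_depth_errors(self, rng):
        t = random_table(rng, n_features=3, n_samples=2, lam=2)
        with pytest.raises(ValueError, match="depth"):
            rarefy(t, depth=10 ** 6, seed=0)

    def test_hypergeometric_mean(self):
        # feature with c of N reads: mean rarefied count over draws ≈ depth*c/N
        col = np.array([300, 700])
        t = FeatureTable(pd.DataFrame({"s": col}, index=["a", "b"]))
        depth, c, n = 100, 300, 1000
        draws = 2000
        rng = np.random.default_rng(0)
        vals = [rarefy(t, depth=depth, seed=rng).counts.loc["a", "s"]
                for _ in range(draws)]
        expected = depth * c / n
        var = depth * (c / n) * (1 - c / n) * (n - depth) / (n - 1)
        se = np.sqrt(var / draws)
        assert abs(np.mean(vals) - expected) < 3 * se


class TestAbundanceFilterAndScaling:
    def test_boundary(self):
        t = FeatureTable(pd.DataFrame({"s": [24, 25, 26]},
                                      index=["a", "b", "c"]))
        assert abundance_filter(t, 25).feature_ids == ["b", "c"]

    def test_zero_threshold_identity(self, rng):
        t = random_table(rng)
        assert abundance_filter(t, 0) == t

    def test_matches_row_sum_oracle(self, rng):
        t = random_table(rng, n_features=40, lam=6)
        out = abundance_filter(t, 30)
        assert out.feature_ids == [
            f for f in t.feature_ids if t.counts.loc[f].sum() >= 30]

    def test_scaling_rows_sum_to_one(self, rng):
        t = random_table(rng, lam=9)
        t = abundance_filter(t, 1)
        scaled = scale_by_feature_total(t)
        np.testing.assert_allclose(scaled.sum(axis=1), 1.0)
        t2 = FeatureTable(pd.DataFrame({"s1": [2], "s2": [3], "s3": [5]},
                                       index=["f"]))
        np.testing.assert_allclose(
            scale_by_feature_total(t2).loc["f"].to_numpy(), [0.2, 0.3, 0.5])

    def test_zero_total_feature_errors(self):
        t = FeatureTable(pd.DataFrame({"s": [0, 5]}, index=["z", "a"]))
        with pytest.raises(ValueError, match="zero-total"):
            scale_by_feature_total(t)


class TestWard:
    def test_duplicate_rows_merge_first_at_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        z = ward_cluster(x)
        assert set(z[0, :2].astype(int)) == {0, 1}
        assert z[0, 2] == pytest.approx(0.0)

    def test_line_points_first_merge(self):
        x = np.array([[0.0], [1.0], [10.0]])
        z = ward_cluster(x)
        assert set(z[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("trial", range(6))
    def test_cuts_match_exhaustive_agglomeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 9))
        x = rng.normal(size=(n, 3))
        z = ward_cluster(x)
        oracle = ward_oracle_partitions(x)
        for k in range(1, n + 1):
            mine = _partition_from_labels(cut_tree(z, k))
            assert mine == oracle[k], f"k={k}"

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            ward_cluster(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestSilhouette:
    def test_two_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.05, (10, 3)),
                       rng.normal(8, 0.05, (10, 3))])
        k, prof = silhouette_select_k(x)
        assert k == 2
        assert prof[2] > 0.95

    def test_four_planted_blobs(self, rng):
        centers = np.eye(4) * 6
        x = np.vstack([rng.normal(c, 0.3, (8, 4)) for c in centers])
        k, _ = silhouette_select_k(x)
        assert k == 4

    def test_singleton_cluster_counts_as_zero(self):
        # one far outlier forms a singleton at k=2; its width is 0 by
        # convention, so the remaining points drive the mean
        from phyllodyn.succession import _silhouette_mean
        from scipy.spatial.distance import pdist, squareform

        x = np.array([[0.0], [0.1], [0.2], [50.0]])
        d = squareform(pdist(x))
        labels = np.array([1, 1, 1, 2])
        val = _silhouette_mean(d, labels)
        manual = []
        for i in range(3):
            a = np.mean([d[i, j] for j in range(3) if j != i])
            b = d[i, 3]
            manual.append((b - a) / max(a, b))
        assert val == pytest.approx((sum(manual) + 0.0) / 4)

    def test_identical_rows_error(self):
        with pytest.raises(ValueError, match="identical"):
            silhouette_select_k(np.ones((5, 3)))


class TestClusterSupport:
    def _leaf(self, paper_data):
        table, meta, tax, truth = paper_data
        from phyllodyn.decontam import classify_blank_features, remove_external
        from phyllodyn.preprocess import preprocess

        tbl, _ = preprocess(table, tax)
        calls = classify_blank_features(tbl, meta, tax)
        clean, _ = remove_external(tbl, calls, meta)
        ids = [s for s in meta.samples_where(compartment="leaf", city="Antwerp")
               if s in set(clean.sample_ids)]
        return clean.select_samples(ids).drop_empty_features(), meta, truth

    def test_single_replicate_unit_support(self, paper_data):
        leaf, meta, truth = self._leaf(paper_data)
        res = SuccessionClustering(leaf, n_replicates=1, depth=912,
                                   min_total=25).fit(seed=0)
        sup = res.support.loc[res.assignment.index]
        assert ((sup == 1.0).sum(axis=1) == 1).all()
        assert ((sup == 0.0).sum(axis=1) == res.reference_k - 1).all()

    def test_identity_rarefaction_support_is_unit(self, rng):
        t = random_table(rng, n_features=12, n_samples=6, lam=50)
        # make all samples exactly the same total so rarefaction = identity
        scale = t.sample_sums().min()
        cols = {}
        for s in t.sample_ids:
            col = t.counts[s].to_numpy().astype(float)
            col = np.floor(col * scale / col.sum()).astype(int)
            col[0] += scale - col.sum()
            cols[s] = col
        eq = FeatureTable(pd.DataFrame(cols, index=t.feature_ids))
        res = SuccessionClustering(eq, n_replicates=2, depth=int(scale),
                                   min_total=0, k=3).fit(seed=5)
        sup = res.support
        assert ((sup == 1.0).sum(axis=1) == 1).all()

    def test_support_rows_sum_to_one_when_always_retained(self, paper_data):
        leaf, meta, truth = self._leaf(paper_data)
        res = SuccessionClustering(leaf, n_replicates=20, depth=912,
                                   min_total=25).fit(seed=3)
        always = res.n_replicates_included[
            res.n_replicates_included == res.n_replicates].index
        assert len(always) > 0
        np.testing.assert_allclose(res.support.loc[always].sum(axis=1), 1.0)
        # support values are multiples of 1/n_replicates
        vals = res.support.loc[always].to_numpy() * res.n_replicates
        np.testing.assert_allclose(vals, np.round(vals), atol=1e-9)

    def test_bit_reproducible_for_fixed_seed(self, paper_data):
        leaf, meta, truth = self._leaf(paper_data)
        r1 = SuccessionClustering(leaf, n_replicates=10, depth=912,
                                  min_total=25).fit(seed=11)
        r2 = SuccessionClustering(leaf, n_replicates=10, depth=912,
                                  min_total=25).fit(seed=11)
        pd.testing.assert_frame_equal(r1.support, r2.support)
        pd.testing.assert_series_equal(r1.assignment, r2.assignment)

    def test_recovers_planted_clusters(self, paper_data):
        leaf, meta, truth = self._leaf(paper_data)
        res = SuccessionClustering(leaf, n_replicates=50, depth=912,
                                   min_total=25).fit(seed=2)
        assert res.reference_k == 4
        planted = truth.cluster_labels.loc[res.assignment.index]
        mask = planted.isin(["general", "early", "middle", "late"])
        ari = adjusted_rand_score(planted[mask], res.assignment[mask])
        assert ari >= 0.9
        assert res.assignment_support().median() >= 0.9

    def test_temporal_naming_matches_truth(self, paper_data):
        leaf, meta, truth = self._leaf(paper_data)
        res = SuccessionClustering(leaf, n_replicates=30, depth=912,
                                   min_total=25).fit(seed=2)
        names = name_clusters(leaf, res, meta)
        planted = truth.cluster_labels.loc[res.assignment.index]
        # majority planted label within each named cluster must agree
        for c, nm in names.items():
            members = res.assignment.index[res.assignment == c]
            if len(members) == 0:
                continue
            major = planted.loc[members].mode().iloc[0]
            assert major == nm


class TestClusterTimeseries:
    def test_fractions_sum_to_one(self, paper_data):
        table, meta, tax, truth = paper_data
        ids = meta.samples_where(compartment="leaf", city="Antwerp")
        leaf = table.select_samples(ids).drop_empty_features()
        res = SuccessionClustering(leaf, n_replicates=5, depth=912,
                                   min_total=25).fit(seed=1)
        ts = cluster_timeseries(leaf, res, meta)
        sums = ts.groupby("sample_id")["rel_abundance"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_all_features_one_cluster(self, rng):
        t = random_table(rng, n_features=8, n_samples=4, lam=40)
        names = t.sample_ids
        meta = simple_metadata(names, trees=["T1"] * 4, days=[0, 7, 14, 21])
        res = SuccessionClustering(t, n_replicates=3, depth=1, min_total=0,
                                   k=2).fit(seed=0)
        ts = cluster_timeseries(t, res, meta)
        other = ts[ts["cluster"] == "other"]["rel_abundance"]
        clus = ts[ts["cluster"] != "other"].groupby("sample_id")["rel_abundance"].sum()
        np.testing.assert_allclose(clus + other.to_numpy(), 1.0, atol=1e-9)
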