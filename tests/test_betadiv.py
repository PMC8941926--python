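"""Bray-Curtis, PCoA, PERMANOVA and PERMDISP2 against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bray
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.distance import permdisp as skbio_permdisp

from phyllodyn.betadiv import Permanova, Permdisp, bray_curtis, pcoa


def brute_force_permanova_f(d2, labels):
    """One-way pseudo-F from the within-group squared-distance formula —
    an algebraic route independent of the hat-matrix implementation."""
    n = len(labels)
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def exhaustive_permanova_p(d2, labels):
    obs = brute_force_permanova_f(d2, labels)
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        f = brute_force_permanova_f(d2, [labels[i] for i in perm])
        hits += f >= obs - 1e-12
        total += 1
    return hits / total


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        x = np.array([[1, 2, 3], [1, 2, 3], [0, 0, 9]], dtype=float)
        dm = bray_curtis(x, relative=False)
        assert dm.data[0, 1] == pytest.approx(0.0)
        x2 = np.array([[5, 0], [0, 7]], dtype=float)
        assert bray_curtis(x2, relative=False).data[0, 1] == pytest.approx(1.0)

    def test_formula_example(self):
        x = np.array([[2, 0, 1], [1, 1, 1]], dtype=float)
        assert bray_curtis(x, relative=False).data[0, 1] == pytest.approx(1 / 3)

    def test_matches_scipy_oracle(self, rng):
        x = rng.poisson(10, size=(8, 30)).astype(float) + 0.1
        dm = bray_curtis(x, relative=False)
        for i, j in itertools.combinations(range(8), 2):
            assert dm.data[i, j] == pytest.approx(scipy_bray(x[i], x[j]))

    def test_rescaling_invariance_on_relative(self, rng):
        x = rng.poisson(20, size=(5, 12)).astype(float) + 1
        d1 = bray_curtis(x, relative=True)
        d2 = bray_curtis(x * np.array([1, 7, 3, 2, 11.0])[:, None], relative=True)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)

    def test_all_zero_sample_named(self):
        x = np.array([[1, 1], [0, 0]], dtype=float)
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(x, relative=False, sample_ids=["ok", "empty"])


class TestPCoA:
    def test_three_equidistant_points(self):
        d = np.full((3, 3), 0.7)
        np.fill_diagonal(d, 0.0)
        ord_ = pcoa(DistanceMatrix(d))
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1])

    def test_line_recovered_from_euclidean_distances(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ord_ = pcoa(DistanceMatrix(d))
        assert (ord_.eigenvalues > 1e-9).sum() == 1
        rec = ord_.coordinates.iloc[:, 0].to_numpy()
        rec = rec - rec[0]
        if rec[-1] < 0:
            rec = -rec
        np.testing.assert_allclose(rec, pts, atol=1e-9)

    def test_duplicate_samples_coincide(self, rng):
        x = rng.normal(size=(4, 5))
        x = np.vstack([x, x[0]])
        dm = DistanceMatrix(squareform(pdist(x)))
        ord_ = pcoa(dm)
        np.testing.assert_allclose(
            ord_.coordinates.iloc[0].to_numpy(),
            ord_.coordinates.iloc[4].to_numpy(),
            atol=1e-8,
        )


class TestPermanova:
    def _dm(self, x):
        return DistanceMatrix(squareform(pdist(x)),
                              ids=[f"s{i}" for i in range(len(x))])

    def test_perfect_separation_r2_one(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=dm.ids)
        res = Permanova(dm, meta, ["g"]).fit(n_permutations=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0)
        assert res.table.loc["Residual", "sum_of_squares"] == pytest.approx(0.0)

    @pytest.mark.parametrize("n,trial", [(6, 0), (6, 1), (7, 2), (8, 3)])
    def test_exact_p_matches_exhaustive_enumeration(self, n, trial):
        rng = np.random.default_rng(100 + trial)
        x = rng.normal(size=(n, 4))
        x[: n // 2] += rng.normal() * 1.5
        dm = self._dm(x)
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        mine = Permanova(dm, meta, ["g"]).fit(method="exact")
        oracle = exhaustive_permanova_p(dm.data ** 2, labels)
        assert mine.table.loc["g", "p_value"] == pytest.approx(oracle, abs=1e-12)
        assert mine.table.loc["g", "pseudo_F"] == pytest.approx(
            brute_force_permanova_f(dm.data ** 2, labels))

    def test_matches_skbio_single_factor(self, rng):
        x = rng.normal(size=(14, 6))
        x[:7] += 1.0
        dm = self._dm(x)
        meta = pd.DataFrame({"g": ["a"] * 7 + ["b"] * 7}, index=dm.ids)
        mine = Permanova(dm, meta, ["g"]).fit(n_permutations=499, seed=3)
        sk = skbio_permanova(dm, meta, column="g", permutations=499)
        assert mine.table.loc["g", "pseudo_F"] == pytest.approx(
            sk["test statistic"])

    def test_ss_decomposition_sums_to_total(self, rng):
        x = rng.normal(size=(20, 5))
        dm = self._dm(x)
        meta = pd.DataFrame(
            {
                "g": (["a", "b"] * 10),
                "h": ["u"] * 5 + ["v"] * 5 + ["w"] * 10,
                "z": rng.normal(size=20),
            },
            index=dm.ids,
        )
        res = Permanova(dm, meta, ["g", "h", "z", "g:h"]).fit(
            n_permutations=49, seed=0)
        parts = res.table.loc[res.table.index != "Total", "sum_of_squares"].sum()
        total = res.table.loc["Total", "sum_of_squares"]
        assert parts == pytest.approx(total, rel=1e-8)
        assert res.table["R2"].drop(index="Total").sum() == pytest.approx(1.0)

    def test_single_level_factor_errors(self, rng):
        x = rng.normal(size=(6, 3))
        dm = self._dm(x)
        meta = pd.DataFrame({"g": ["a"] * 6}, index=dm.ids)
        with pytest.raises(ValueError, match="single level"):
            Permanova(dm, meta, ["g"])

    def test_p_value_floor(self, rng):
        x = rng.normal(size=(10, 3))
        x[:5] += 5
        dm = self._dm(x)
        meta = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=dm.ids)
        res = Permanova(dm, meta, ["g"]).fit(n_permutations=99, seed=0)
        assert res.table.loc["g", "p_value"] >= 1 / 100


class TestPermdisp:
    def test_zero_dispersion_within_groups(self):
        x = np.array([[0, 0], [0, 0], [5, 5], [5, 5.0]])
        dm = DistanceMatrix(squareform(pdist(x)),
                            ids=["a1", "a2", "b1", "b2"])
        meta = pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=dm.ids)
        res = Permdisp(dm, meta, "g").fit(n_permutations=19, seed=0)
        assert res.distances.abs().max() == pytest.approx(0.0, abs=1e-10)

    def test_detects_scaled_spread(self, rng):
        x = rng.normal(size=(40, 4))
        x[20:] *= 3.0
        dm = DistanceMatrix(squareform(pdist(x)),
                            ids=[f"s{i}" for i in range(40)])
        meta = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20}, index=dm.ids)
        res = Permdisp(dm, meta, "g").fit(n_permutations=199, seed=1)
        assert res.p_value < 0.05
        assert res.group_means["b"] > res.group_means["a"]

    def test_matches_skbio_centroid_statistic(self, rng):
        x = rng.normal(size=(16, 5))
        x[8:] *= 2.0
        dm = DistanceMatrix(squareform(pdist(x)),
                            ids=[f"s{i}" for i in range(16)])
        meta = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8}, index=dm.ids)
        mine = Permdisp(dm, meta, "g").fit(n_permutations=99, seed=0)
        sk = skbio_permdisp(dm, meta, column="g", test="centroid",
                            permutations=99)
        assert mine.f_stat == pytest.approx(sk["test statistic"])

    def test_singleton_group_errors(self, rng):
        x = rng.normal(size=(5, 3))
        dm = DistanceMatrix(squareform(pdist(x)),
                            ids=[f"s{i}" for i in range(5)])
        meta = pd.DataFrame({"g": ["a", "a", "a", "a", "b"]}, index=dm.ids)
        with pytest.raises(ValueError, match="singleton"):
            Permdisp(dm, meta, "g")
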