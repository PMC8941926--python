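"""Core genera, CLR transform and IndVal indicator analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phyllodyn.data_model import FeatureTable
from phyllodyn.compartment_taxa import (
    clr_transform,
    core_taxa,
    indicator_analysis,
)

from conftest import simple_metadata


def _meta(compartments, days=None, trees=None):
    names = [f"s{i}" for i in range(len(compartments))]
    m = simple_metadata(names, trees=trees or ["T1"] * len(names),
                        days=days or [42] * len(names))
    m.df["compartment"] = compartments
    return names, m


class TestCoreTaxa:
    def test_presence_and_prevalence_boundaries(self):
        names, meta = _meta(["leaf"] * 20)
        counts = pd.DataFrame(
            {s: [11, 10, 50] for s in names},
            index=["core_g", "ten_g", "partial_g"],
        )
        counts.loc["partial_g", names[0]] = 0  # present in 19/20 = 0.95
        t = FeatureTable(counts)
        res = core_taxa(t, meta, presence_min_reads=10, prevalence_threshold=0.95)
        core = res.core_genera("leaf")
        assert "core_g" in core  # 11 reads everywhere
        assert "ten_g" not in core  # exactly 10 reads: not "more than 10"
        assert "partial_g" not in core  # 0.95 is not "> 0.95"

    def test_monotone_in_thresholds(self, rng):
        names, meta = _meta(["leaf"] * 10 + ["trunk"] * 10)
        t = FeatureTable(pd.DataFrame(
            rng.poisson(20, (15, 20)),
            index=[f"g{i}" for i in range(15)], columns=names))
        base = set()
        for comp in ("leaf", "trunk"):
            base |= {(comp, g) for g in core_taxa(t, meta, 10, 0.9).core_genera(comp)}
        for pmr, prev in [(20, 0.9), (10, 0.95), (25, 0.99)]:
            stricter = set()
            res = core_taxa(t, meta, pmr, prev)
            for comp in ("leaf", "trunk"):
                stricter |= {(comp, g) for g in res.core_genera(comp)}
            assert stricter <= base

    def test_empty_compartment_errors(self):
        names, meta = _meta(["leaf"] * 3)
        t = FeatureTable(pd.DataFrame({s: [5] for s in names}, index=["g"]))
        meta2 = meta.subset([])
        with pytest.raises((ValueError, KeyError)):
            core_taxa(t.select_samples([]), meta2)


class TestCLR:
    def test_uniform_sample_is_zero(self):
        t = FeatureTable(pd.DataFrame({"s": [7, 7, 7]}, index=list("abc")))
        np.testing.assert_allclose(clr_transform(t, 1.0)["s"], 0.0)

    def test_columns_sum_to_zero(self, rng):
        from conftest import random_table

        t = random_table(rng, n_features=12, n_samples=5)
        out = clr_transform(t, 0.5)
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-10)

    def test_scale_invariance_in_small_pseudocount_limit(self):
        t1 = FeatureTable(pd.DataFrame({"s": [10, 20, 40]}, index=list("abc")))
        t2 = FeatureTable(pd.DataFrame({"s": [20, 40, 80]}, index=list("abc")))
        c1 = clr_transform(t1, 1e-9)["s"].to_numpy()
        c2 = clr_transform(t2, 1e-9)["s"].to_numpy()
        np.testing.assert_allclose(c1, c2, atol=1e-6)

    def test_nonpositive_pseudocount_errors(self):
        t = FeatureTable(pd.DataFrame({"s": [1]}, index=["a"]))
        with pytest.raises(ValueError):
            clr_transform(t, 0.0)


def indval_oracle(values, codes, combo):
    """Direct IndVal.g for one feature row and one group combination."""
    groups = sorted(set(codes))
    means = {g: values[codes == g].mean() for g in groups}
    denom = sum(means.values())
    a = sum(means[g] for g in combo) / denom if denom > 0 else 0.0
    b = (values[np.isin(codes, list(combo))] > 0).mean()
    return np.sqrt(a * b)


class TestIndicatorAnalysis:
    def _data(self):
        comps = ["leaf"] * 3 + ["trunk"] * 3 + ["branch"] * 3
        names, meta = _meta(comps, trees=[f"T{i}" for i in range(9)])
        vals = pd.DataFrame(
            {
                s: [
                    5.0 if c == "leaf" else 0.0,  # perfect leaf indicator
                    3.0,  # uniform everywhere
                    4.0 if c in ("trunk", "branch") else 0.0,  # pair indicator
                ]
                for s, c in zip(names, comps)
            },
            index=["leafy", "everywhere", "woody"],
        )
        return vals, meta

    def test_perfect_indicator_statistic_one(self):
        vals, meta = self._data()
        res = indicator_analysis(vals, meta, n_permutations=99, seed=0,
                                 final_timepoint_only=False)
        t = res.table
        row = t[(t["genus"] == "leafy") & (t["groups"] == "leaf")].iloc[0]
        assert row["stat"] == pytest.approx(1.0)
        woody = t[(t["genus"] == "woody") & (t["groups"] == "trunk+branch")]
        assert woody.iloc[0]["stat"] == pytest.approx(1.0)

    def test_uniform_taxon_specificity(self):
        vals, meta = self._data()
        res = indicator_analysis(vals, meta, n_permutations=49, seed=0,
                                 final_timepoint_only=False)
        t = res.table
        for comp in ("leaf", "trunk", "branch"):
            row = t[(t["genus"] == "everywhere") & (t["groups"] == comp)].iloc[0]
            assert row["A"] == pytest.approx(1 / 3)
            assert row["stat"] == pytest.approx(np.sqrt(1 / 3))

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # 6 samples, two groups of 3: compare against all 6! label orders
        comps = ["leaf"] * 3 + ["trunk"] * 3
        names, meta = _meta(comps, trees=[f"T{i}" for i in range(6)])
        rng = np.random.default_rng(3)
        row = rng.gamma(2.0, size=6)
        vals = pd.DataFrame([row], index=["g"], columns=names)
        codes = np.array([0, 0, 0, 1, 1, 1])
        combos = [(0,), (1,)]
        obs = {c: indval_oracle(row, codes, c) for c in combos}
        hits = {c: 0 for c in combos}
        total = 0
        for perm in itertools.permutations(range(6)):
            pc = codes[list(perm)]
            for c in combos:
                hits[c] += indval_oracle(row, pc, c) >= obs[c] - 1e-12
            total += 1
        # package p with near-exhaustive sampled permutations converges to
        # the enumeration value (add-one estimator, so compare loosely)
        res = indicator_analysis(vals, meta, n_permutations=4999, seed=1,
                                 final_timepoint_only=False)
        t = res.table
        for c, name in [((0,), "leaf"), ((1,), "trunk")]:
            mine = t[(t["genus"] == "g") & (t["groups"] == name)].iloc[0]["p_value"]
            assert mine == pytest.approx(hits[c] / total, abs=0.03)

    def test_invariant_to_relabeling_nontarget_groups(self):
        vals, meta = self._data()
        res1 = indicator_analysis(vals, meta, n_permutations=9, seed=0,
                                  final_timepoint_only=False)
        meta2 = meta.subset(meta.sample_ids)
        swap = {"trunk": "branch", "branch": "trunk", "leaf": "leaf"}
        meta2.df["compartment"] = meta2.df["compartment"].map(swap)
        res2 = indicator_analysis(vals, meta2, n_permutations=9, seed=0,
                                  final_timepoint_only=False)
        s1 = res1.table[(res1.table["genus"] == "leafy")
                        & (res1.table["groups"] == "leaf")].iloc[0]["stat"]
        s2 = res2.table[(res2.table["genus"] == "leafy")
                        & (res2.table["groups"] == "leaf")].iloc[0]["stat"]
        assert s1 == pytest.approx(s2)

    def test_final_timepoint_restriction(self):
        comps = ["leaf"] * 4
        names, meta = _meta(comps, days=[7, 7, 42, 42],
                            trees=["T1", "T2", "T1", "T2"])
        t = FeatureTable(pd.DataFrame(
            {s: [10, 20] for s in names}, index=["a", "b"]))
        meta.df.loc[names[2:], "compartment"] = "trunk"
        meta.df.loc[names[:2], "compartment"] = "leaf"
        # with final-timepoint-only there is just one group left -> error
        with pytest.raises(ValueError):
            indicator_analysis(t, meta, n_permutations=9, seed=0,
                               final_timepoint_only=True)

    def test_clr_shift_mode_runs_on_counts(self, tiny_data):
        table, meta, tax, truth = tiny_data
        from phyllodyn.data_model import aggregate_to_rank

        genus = aggregate_to_rank(table.drop_samples(meta.blank_ids()), tax,
                                  "genus")
        res = indicator_analysis(genus, meta, n_permutations=49, seed=0)
        assert (res.table["stat"].between(0, 1 + 1e-9)).all()
        assert (res.table["A"].between(0, 1)).all()
        assert (res.table["B"].between(0, 1)).all()
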