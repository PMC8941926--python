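"""Self-validation experiments: oracle equivalence, type-I calibration and
ground-truth recovery on synthetic data.

Each function runs an experiment end-to-end through the public pipeline and
returns a dictionary of summary metrics. The oracles here (exhaustive
PERMANOVA enumeration via the group-sum-of-squares identity, all-pairs
Kendall tau, greedy minimum-variance agglomeration from raw centroids) are
deliberately written along different algebraic routes than the production
implementations they check.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from . import betadiv, decontam, dynamics, overlap, synth
from .betadiv import Permanova, Permdisp, bray_curtis
from .data_model import FeatureTable
from .dynamics import DissimilaritySeries, kendall_trend
from .preprocess import preprocess
from .succession import SuccessionClustering, cut_tree, ward_cluster


def _child_seeds(seed: int | None, n: int, salt: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([salt, seed or 0]))
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _permanova_f_groupsums(d2: np.ndarray, labels: list) -> float:
    """Pseudo-F from SS_total − SS_within via pairwise squared distances."""
    n = len(labels)
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def _permanova_p_exhaustive(d2: np.ndarray, labels: list) -> float:
    obs = _permanova_f_groupsums(d2, labels)
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        hits += _permanova_f_groupsums(d2, [labels[i] for i in perm]) >= obs - 1e-12
        total += 1
    return hits / total


def _kendall_tau_allpairs(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0:
            tx += 1
            ty += dy == 0
        elif dy == 0:
            ty += 1
        elif dx == dy:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


def _ward_partitions_greedy(x: np.ndarray) -> dict[int, set[frozenset]]:
    """Greedy minimum-variance agglomeration recomputing centroids from the
    raw coordinates at every step (no Lance-Williams recursion)."""
    clusters = [frozenset([i]) for i in range(len(x))]
    parts = {len(clusters): set(clusters)}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = x[list(clusters[a])].mean(axis=0)
                cb = x[list(clusters[b])].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                delta = na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        parts[len(clusters)] = set(clusters)
    return parts


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def permanova_oracle_check(seed: int | None = 0, n_instances: int = 20) -> dict:
    """Exact-enumeration equivalence and SS-decomposition closure."""
    seeds = _child_seeds(seed, n_instances, salt=1)
    max_p_diff = 0.0
    for s in seeds:
        rng = np.random.default_rng(s)
        n = int(rng.integers(6, 9))
        x = rng.normal(size=(n, 4))
        x[: n // 2] += rng.normal() * 1.2
        d = squareform(pdist(x))
        ids = [f"s{i}" for i in range(n)]
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        meta = pd.DataFrame({"g": labels}, index=ids)
        from skbio import DistanceMatrix

        res = Permanova(DistanceMatrix(d, ids=ids), meta, ["g"]).fit(method="exact")
        oracle = _permanova_p_exhaustive(d ** 2, labels)
        max_p_diff = max(max_p_diff, abs(res.table.loc["g", "p_value"] - oracle))

    # SS closure on larger multi-term models
    max_ss_err = 0.0
    for s in seeds[:5]:
        rng = np.random.default_rng(s)
        x = rng.normal(size=(20, 5))
        d = squareform(pdist(x))
        ids = [f"s{i}" for i in range(20)]
        from skbio import DistanceMatrix

        meta = pd.DataFrame(
            {"g": ["a", "b"] * 10, "h": ["u"] * 10 + ["v"] * 10,
             "z": rng.normal(size=20)},
            index=ids,
        )
        res = Permanova(DistanceMatrix(d, ids=ids), meta,
                        ["g", "h", "z", "g:h"]).fit(n_permutations=9, seed=s)
        parts = res.table.loc[res.table.index != "Total", "sum_of_squares"].sum()
        total = res.table.loc["Total", "sum_of_squares"]
        max_ss_err = max(max_ss_err, abs(parts - total) / abs(total))
    return {
        "permanova_exact_p_max_abs_diff": float(max_p_diff),
        "permanova_ss_closure_max_rel_err": float(max_ss_err),
        "n": n_instances,
    }


def kendall_ward_oracle_check(seed: int | None = 0, n_series: int = 200,
                              n_ward: int = 25) -> dict:
    """All-pairs Kendall tau equivalence and Ward-cut equivalence."""
    seeds = _child_seeds(seed, n_series, salt=2)
    max_tau_diff = 0.0
    for s in seeds:
        rng = np.random.default_rng(s)
        n = int(rng.integers(5, 51))
        x = rng.integers(0, 20, n).astype(float)
        if np.all(x == x[0]):
            x[0] += 1.0
        y = rng.normal(size=n)
        rec = pd.DataFrame({"tree_id": "T", "compartment": "leaf",
                            "time_days": x, "dissimilarity": y,
                            "kind": "consecutive"})
        tau = kendall_trend(DissimilaritySeries(rec, "consecutive")).tau
        max_tau_diff = max(max_tau_diff, abs(tau - _kendall_tau_allpairs(x, y)))

    mismatches = 0
    total_cuts = 0
    for s in _child_seeds(seed, n_ward, salt=3):
        rng = np.random.default_rng(s)
        n = int(rng.integers(4, 9))
        x = rng.normal(size=(n, 3))
        z = ward_cluster(x)
        oracle = _ward_partitions_greedy(x)
        for k in range(1, n + 1):
            labels = cut_tree(z, k)
            mine = {}
            for i, lab in enumerate(labels):
                mine.setdefault(lab, set()).add(i)
            total_cuts += 1
            if {frozenset(v) for v in mine.values()} != oracle[k]:
                mismatches += 1
    return {
        "kendall_tau_max_abs_diff": float(max_tau_diff),
        "ward_cut_mismatch_fraction": mismatches / total_cuts,
        "n": n_series,
    }


def type1_calibration(seed: int | None = 0, n_datasets: int = 500,
                      n_permutations: int = 999) -> dict:
    """Null rejection rates of PERMANOVA, PERMDISP2 and the Kendall trend
    test on the null_model preset (no planted effects)."""
    seeds = _child_seeds(seed, n_datasets, salt=4)
    rej = {"permanova": 0, "permdisp": 0, "kendall": 0}
    for i, s in enumerate(seeds):
        table, meta, tax, truth = synth.generate(synth.preset("null_model"),
                                                 seed=s)
        dm = bray_curtis(table)
        p = Permanova(dm, meta, ["tree_id"]).fit(
            n_permutations=n_permutations, seed=s + 1)
        rej["permanova"] += p.table.loc["tree_id", "p_value"] <= 0.05
        d = Permdisp(dm, meta, "tree_id").fit(
            n_permutations=n_permutations, seed=s + 2)
        rej["permdisp"] += d.p_value <= 0.05
        series = dynamics.consecutive_dissimilarity(table, meta, "leaf",
                                                    disjoint=True)
        rej["kendall"] += kendall_trend(series).p_value <= 0.05
    return {
        "permanova_null_rejection_rate": rej["permanova"] / n_datasets,
        "permdisp_null_rejection_rate": rej["permdisp"] / n_datasets,
        "kendall_null_rejection_rate": rej["kendall"] / n_datasets,
        "n": n_datasets,
    }


def _clean_antwerp_leaf(seed: int):
    """Generate a study-scale data set and run it through preprocessing and
    decontamination; return the Antwerp leaf table plus context."""
    table, meta, tax, truth = synth.generate(synth.preset("paper_like"),
                                             seed=seed)
    tbl, _ = preprocess(table, tax)
    calls = decontam.classify_blank_features(tbl, meta, tax)
    clean, _ = decontam.remove_external(tbl, calls, meta)
    ids = [s for s in meta.samples_where(compartment="leaf", city="Antwerp")
           if s in set(clean.sample_ids)]
    leaf = clean.select_samples(ids).drop_empty_features()
    return leaf, clean, meta, tax, truth


def succession_recovery(seed: int | None = 0, n_seeds: int = 20,
                        n_replicates: int = 100) -> dict:
    """k-selection, planted-cluster recovery (ARI) and support levels."""
    seeds = _child_seeds(seed, n_seeds, salt=5)
    k4 = 0
    aris = []
    supports = []
    for s in seeds:
        leaf, clean, meta, tax, truth = _clean_antwerp_leaf(s)
        res = SuccessionClustering(leaf, n_replicates=n_replicates, depth=912,
                                   min_total=25).fit(seed=s + 1)
        k4 += res.reference_k == 4
        planted = truth.cluster_labels.loc[res.assignment.index]
        mask = planted.isin(["general", "early", "middle", "late"])
        aris.append(adjusted_rand_score(planted[mask], res.assignment[mask]))
        from .succession import name_clusters

        names = name_clusters(leaf, res, meta)
        correct = [f for f in res.assignment.index[mask]
                   if names.get(res.assignment[f]) == planted[f]]
        supports.append(
            float(res.assignment_support().loc[correct].median())
            if correct else 0.0)
    return {
        "succession_k4_count": k4,
        "succession_median_ari": float(np.median(aris)),
        "succession_median_support_correct": float(np.median(supports)),
        "n": n_seeds,
    }


def dynamics_recovery(seed: int | None = 0, n_seeds: int = 100) -> dict:
    """Leaf change-rate decay detection vs woody-compartment null rates."""
    seeds = _child_seeds(seed, n_seeds, salt=6)
    leaf_sig = 0
    trunk_rej = 0
    branch_rej = 0
    for s in seeds:
        table, meta, tax, truth = synth.generate(synth.preset("paper_like"),
                                                 seed=s)
        tbl, _ = preprocess(table, tax)
        calls = decontam.classify_blank_features(tbl, meta, tax)
        clean, _ = decontam.remove_external(tbl, calls, meta)
        ant = [x for x in meta.nonblank().index
               if meta.df.loc[x, "city"] == "Antwerp"
               and x in set(clean.sample_ids)]
        sub = clean.select_samples(ant)
        leaf = dynamics.consecutive_dissimilarity(sub, meta, "leaf")
        tr = kendall_trend(leaf)
        leaf_sig += (tr.tau < 0) and (tr.p_value < 0.05)
        for comp in ("trunk", "branch"):
            series = dynamics.consecutive_dissimilarity(sub, meta, comp,
                                                        disjoint=True)
            rej = kendall_trend(series).p_value <= 0.05
            if comp == "trunk":
                trunk_rej += rej
            else:
                branch_rej += rej
    return {
        "dynamics_leaf_negative_trend_fraction": leaf_sig / n_seeds,
        "dynamics_trunk_null_rejection_rate": trunk_rej / n_seeds,
        "dynamics_branch_null_rejection_rate": branch_rej / n_seeds,
        "n": n_seeds,
    }


def decontam_recovery(seed: int | None = 0, n_seeds: int = 100) -> dict:
    """External-contaminant recovery and presence-threshold coverage."""
    seeds = _child_seeds(seed, n_seeds, salt=7)
    exact = 0
    min_removed = 1.0
    for s in seeds:
        table, meta, tax, truth = synth.generate(synth.preset("tiny"), seed=s)
        calls = decontam.classify_blank_features(table, meta, tax)
        called_ext = {c.feature_id for c in calls if c.call == "external"}
        exact += called_ext == set(truth.external_ids)
        thr = decontam.presence_threshold(table, truth.external_ids, 0.5)
        counts = table.counts.loc[truth.external_ids].to_numpy().ravel()
        counts = counts[counts > 0]
        min_removed = min(min_removed, float((counts <= thr).mean()))
    return {
        "decontam_external_exact_recovery_fraction": exact / n_seeds,
        "decontam_presence_removed_fraction_min": min_removed,
        "n": n_seeds,
    }


def overlap_ubiquity_recovery(seed: int | None = 0, n_seeds: int = 10,
                              n_replicates: int = 30) -> dict:
    """Shared-fraction and ubiquity contrast between the general and late
    clusters; k is fixed at the planted number of clusters."""
    seeds = _child_seeds(seed, n_seeds, salt=8)
    min_shared_gap = np.inf
    min_ubiq_gap = np.inf
    for s in seeds:
        leaf, clean, meta, tax, truth = _clean_antwerp_leaf(s)
        res = SuccessionClustering(leaf, n_replicates=n_replicates, depth=912,
                                   min_total=25, k=4).fit(seed=s + 1)
        from .succession import name_clusters

        names = name_clusters(leaf, res, meta)
        inv = {v: k for k, v in names.items()}
        sets = overlap.presence_sets(clean, meta, "compartment", min_reads=10)
        other = {c: ss for c, ss in sets.items() if c != "leaf"}
        ov = overlap.cluster_compartment_overlap(res, leaf, other, meta)
        shared = {nm: overlap.shared_fraction_of_cluster(ov, inv[nm])
                  for nm in inv}
        ub = overlap.ubiquity(res, clean, meta, scope="one_city",
                              city="Antwerp")
        mu = {names[k]: v for k, v in ub.mean_by_cluster().items()}
        min_shared_gap = min(min_shared_gap, shared["general"] - shared["late"])
        min_ubiq_gap = min(min_ubiq_gap, mu["general"] - mu["late"])
    return {
        "overlap_shared_fraction_gap_min": float(min_shared_gap),
        "ubiquity_gap_min": float(min_ubiq_gap),
        "n": n_seeds,
    }


def determinism_check(seed: int | None = 0) -> dict:
    """Full pipeline twice with one master seed: results must be identical."""
    outs = []
    for _ in range(2):
        table, meta, tax, truth = synth.generate(synth.preset("tiny"),
                                                 seed=seed)
        tbl, _ = preprocess(table, tax)
        calls = decontam.classify_blank_features(tbl, meta, tax)
        clean, _ = decontam.remove_external(tbl, calls, meta)
        ids = [s for s in meta.samples_where(compartment="leaf")
               if s in set(clean.sample_ids)]
        leaf = clean.select_samples(ids).drop_empty_features()
        res = SuccessionClustering(leaf, n_replicates=20, depth=300,
                                   min_total=10, k=4).fit(seed=(seed or 0) + 1)
        outs.append((clean.counts.copy(), res.support.copy(),
                     res.assignment.copy()))
    identical = (
        outs[0][0].equals(outs[1][0])
        and outs[0][1].equals(outs[1][1])
        and outs[0][2].equals(outs[1][2])
    )
    return {"determinism_identical": 1.0 if identical else 0.0, "n": 2}
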