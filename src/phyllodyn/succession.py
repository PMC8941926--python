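"""Rarefaction-bootstrapped co-occurrence clustering of leaf ASVs.

The procedure groups the abundant ASVs of one compartment (typically the
emerging leaves) into co-occurrence clusters that track successional stages,
and quantifies how stable each ASV's cluster membership is under sampling
noise:

1. rarefy every sample without replacement to a common depth (samples below
   the depth are dropped),
2. drop ASVs whose total abundance in the rarefied table is below a
   threshold (default 25 reads),
3. scale each ASV's per-sample abundances by the ASV's total, so every ASV
   becomes a unit-mass temporal/spatial profile,
4. Euclidean distances between ASV profiles → Ward (minimum-variance)
   agglomeration → cut into *k* clusters (*k* chosen once by mean
   silhouette width on the unrarefied reference table, default policy),
5. repeat for many independent rarefactions; per replicate, match clusters
   to the reference clustering by optimal one-to-one overlap assignment;
   the **support** of an ASV for a cluster is the fraction of replicates in
   which it landed there. Every ASV that survived filtering at least once is
   assigned to its highest-support cluster.

`SuccessionClustering(...).fit(seed)` returns a `SuccessionResults` object
carrying the support matrix, assignments, silhouette profile and helpers for
cluster time series and temporal naming (general/early/middle/late).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .data_model import FeatureTable, SampleMetadata


# ---------------------------------------------------------------------------
# pipeline primitives
# ---------------------------------------------------------------------------

def rarefy(
    table: FeatureTable,
    depth: int = 912,
    seed: int | np.random.Generator | None = None,
) -> FeatureTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped. The draw per sample
    is multivariate hypergeometric, so expected rarefied counts are
    ``depth * c / N`` for a feature with ``c`` of the sample's ``N`` reads.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    if not keep:
        raise ValueError(f"no sample reaches the rarefaction depth {depth}")
    cols = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if sums[s] == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.feature_ids)
    return FeatureTable(out, validate=False)


def abundance_filter(table: FeatureTable, min_total: int = 25) -> FeatureTable:
    """Keep features with total abundance >= ``min_total`` (strict
    "less than ``min_total``" removal)."""
    sums = table.feature_sums()
    keep = [f for f in table.feature_ids if sums[f] >= min_total]
    return table.select_features(keep)


def scale_by_feature_total(table: FeatureTable) -> pd.DataFrame:
    """Divide each feature's per-sample abundances by the feature's total.

    Every row becomes a unit-mass profile over samples (rows sum to 1).
    """
    sums = table.feature_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-total feature(s): {list(zero.index)[:10]}")
    return table.counts.div(sums, axis=0)


def ward_cluster(scaled: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward minimum-variance agglomeration (Ward.D2 on Euclidean distances)
    of feature profiles; returns a scipy linkage matrix.

    Ties in the merge objective are resolved by scipy's nearest-neighbour
    chain order, which is deterministic given the input row order.
    """
    x = np.asarray(scaled, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in scaled matrix")
    return linkage(pdist(x), method="ward")


def cut_tree(z: np.ndarray, k: int) -> np.ndarray:
    """Cut a dendrogram into ``k`` flat clusters (labels 1..k)."""
    return fcluster(z, t=k, criterion="maxclust")


def _silhouette_mean(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a square distance matrix.

    Singleton clusters get silhouette 0 by convention.
    """
    n = dist.shape[0]
    uniq = np.unique(labels)
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, masks[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def silhouette_select_k(
    scaled: pd.DataFrame | np.ndarray,
    z: np.ndarray | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> tuple[int, dict[int, float]]:
    """Pick the dendrogram cut maximising mean silhouette width.

    Returns ``(k, profile)`` where profile maps each candidate k to its mean
    silhouette; ties go to the smallest k.
    """
    x = np.asarray(scaled, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 features for silhouette selection")
    dist = squareform(pdist(x))
    if not dist.any():
        raise ValueError("all feature profiles identical; silhouette undefined")
    if z is None:
        z = ward_cluster(x)
    lo, hi = k_range
    hi = min(hi, n - 1)
    if lo > hi:
        raise ValueError(f"k_range {k_range} infeasible for {n} features")
    profile: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels = cut_tree(z, k)
        if len(np.unique(labels)) < 2:
            profile[k] = -1.0
            continue
        profile[k] = _silhouette_mean(dist, labels)
    best = max(profile, key=lambda k: (profile[k], -k))
    return best, profile


# ---------------------------------------------------------------------------
# replicate bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ReplicateClustering:
    index: int
    feature_ids: list[str]
    labels: np.ndarray  # 1..k, parallel to feature_ids
    k: int
    seed: object = None


def _match_to_reference(
    rep: ReplicateClustering,
    ref_labels: pd.Series,
    k_ref: int,
) -> dict[int, int]:
    """Map each replicate cluster to a reference cluster.

    Optimal one-to-one matching on shared-feature counts
    (rectangular assignment); when the replicate has more clusters than the
    reference, leftover clusters map greedily to their best-overlap
    reference cluster.
    """
    k_rep = rep.k
    overlap = np.zeros((k_rep, k_ref))
    ref = ref_labels.reindex(rep.feature_ids)
    for lab_rep, lab_ref in zip(rep.labels, ref.to_numpy()):
        if not np.isnan(lab_ref):
            overlap[lab_rep - 1, int(lab_ref) - 1] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    for c_rep in range(1, k_rep + 1):
        if c_rep not in mapping:
            mapping[c_rep] = int(np.argmax(overlap[c_rep - 1])) + 1
    return mapping


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SuccessionResults:
    """Support matrix, assignments and diagnostics of the bootstrap."""

    def __init__(
        self,
        support: pd.DataFrame,
        assignment: pd.Series,
        n_replicates: int,
        n_replicates_included: pd.Series,
        reference_k: int,
        reference_labels: pd.Series,
        silhouette_profile: dict[int, float] | None,
        k_mismatch_count: int,
        seed,
    ):
        #: features × clusters matrix of support fractions (rows sum to <= 1)
        self.support = support
        #: per-feature argmax cluster label (ties -> lowest cluster index)
        self.assignment = assignment
        self.n_replicates = n_replicates
        self.n_replicates_included = n_replicates_included
        self.reference_k = reference_k
        self.reference_labels = reference_labels
        self.silhouette_profile = silhouette_profile
        #: replicates whose silhouette-selected k differed from the reference
        self.k_mismatch_count = k_mismatch_count
        self.seed = seed

    @property
    def cluster_labels(self) -> list[str]:
        return list(self.support.columns)

    def assignment_support(self) -> pd.Series:
        """Support of each feature for its assigned cluster."""
        return pd.Series(
            {f: self.support.loc[f, c] for f, c in self.assignment.items()},
            name="support",
        )

    def summary(self) -> str:
        counts = self.assignment.value_counts().sort_index()
        lines = [
            f"Rarefaction-bootstrap co-occurrence clustering "
            f"({self.n_replicates} replicates, k = {self.reference_k})",
            f"{len(self.assignment)} ASVs assigned; "
            f"k-mismatch replicates: {self.k_mismatch_count}",
            "cluster sizes: " + ", ".join(f"{c}: {n}" for c, n in counts.items()),
            "median assignment support: "
            f"{self.assignment_support().median():.3f}",
        ]
        if self.silhouette_profile:
            prof = ", ".join(
                f"k={k}: {v:.3f}" for k, v in sorted(self.silhouette_profile.items())
            )
            lines.append("silhouette profile: " + prof)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return self.summary()

    # -- downstream views ----------------------------------------------------
    def cluster_timeseries(
        self, table: FeatureTable, metadata: SampleMetadata
    ) -> pd.DataFrame:
        return cluster_timeseries(table, self, metadata)

    def name_clusters(
        self, table: FeatureTable, metadata: SampleMetadata
    ) -> dict[str, str]:
        return name_clusters(table, self, metadata)

    def top_features(self, table: FeatureTable, n: int = 10) -> pd.DataFrame:
        """Per cluster, the ``n`` most abundant assigned ASVs with their
        support and average relative abundance (percent)."""
        rel = table.relative_abundance()
        mean_rel = rel.loc[[f for f in self.assignment.index if f in rel.index]].mean(axis=1)
        sup = self.assignment_support()
        rows = []
        for c in self.cluster_labels:
            members = [f for f, lab in self.assignment.items() if lab == c]
            members = sorted(members, key=lambda f: -mean_rel.get(f, 0.0))[:n]
            for f in members:
                rows.append((c, f, sup[f], 100.0 * mean_rel.get(f, 0.0)))
        return pd.DataFrame(
            rows, columns=["cluster", "feature_id", "support", "avg_abundance_pct"]
        )


class SuccessionClustering:
    """Model object for the rarefaction-bootstrap clustering of one
    compartment's feature table.

    Parameters
    ----------
    table
        FeatureTable restricted to one compartment's samples (e.g. all leaf
        samples of one city).
    n_replicates, depth, min_total
        Bootstrap size, rarefaction depth (reads/sample) and the minimum
        total abundance for an ASV to enter the co-occurrence analysis,
        applied per rarefied replicate.
    k
        Number of clusters; ``None`` (default) selects k once on the
        unrarefied reference table by mean silhouette width over
        ``k_range``.
    reselect_k_per_replicate
        Re-run silhouette selection inside every replicate (slower; replicate
        clusterings with a different k are matched greedily and counted in
        ``k_mismatch_count``).
    """

    def __init__(
        self,
        table: FeatureTable,
        n_replicates: int = 1000,
        depth: int = 912,
        min_total: int = 25,
        k: int | None = None,
        k_range: tuple[int, int] = (2, 8),
        reselect_k_per_replicate: bool = False,
    ):
        self.table = table
        self.n_replicates = int(n_replicates)
        self.depth = int(depth)
        self.min_total = int(min_total)
        self.k = k
        self.k_range = k_range
        self.reselect_k = reselect_k_per_replicate

    def _reference(self) -> tuple[pd.Series, int, dict[int, float] | None]:
        # Reference clustering on the *expected* rarefied table: samples at
        # depth, counts scaled deterministically to depth * c / N. This keeps
        # the abundance threshold on the same scale as the replicates while
        # involving no randomness.
        sums = self.table.sample_sums()
        keep = [s for s in self.table.sample_ids if sums[s] >= self.depth]
        if not keep:
            raise ValueError(f"no sample reaches the rarefaction depth {self.depth}")
        expected = self.table.counts[keep] * (self.depth / sums[keep])
        totals = expected.sum(axis=1)
        feats = totals.index[totals >= self.min_total]
        if len(feats) < 3:
            raise ValueError(
                f"only {len(feats)} features pass the abundance filter"
            )
        expected = expected.loc[feats]
        scaled = expected.div(expected.sum(axis=1), axis=0)
        ref_table = FeatureTable(
            self.table.counts.loc[feats, keep], validate=False
        )
        z = ward_cluster(scaled)
        profile = None
        if self.k is None:
            k, profile = silhouette_select_k(scaled, z, self.k_range)
        else:
            k = int(self.k)
        labels = pd.Series(cut_tree(z, k), index=ref_table.feature_ids)
        return labels, k, profile

    def _replicate(self, idx: int, rng: np.random.Generator) -> ReplicateClustering | None:
        try:
            t = rarefy(self.table, self.depth, rng)
        except ValueError:
            return None
        t = abundance_filter(t, self.min_total).drop_empty_features()
        if t.shape[0] < 3:
            return None
        scaled = scale_by_feature_total(t)
        z = ward_cluster(scaled)
        if self.reselect_k:
            k, _ = silhouette_select_k(scaled, z, self.k_range)
        else:
            k = self._k_fixed
        k = min(k, t.shape[0])
        labels = cut_tree(z, k)
        return ReplicateClustering(idx, t.feature_ids, labels, k)

    def fit(self, seed: int | None = None) -> SuccessionResults:
        ref_labels, k_ref, profile = self._reference()
        self._k_fixed = k_ref
        cluster_cols = [f"C{c}" for c in range(1, k_ref + 1)]
        # every table feature may survive some replicate's filter, not only
        # those in the reference set
        all_features = list(self.table.feature_ids)
        fidx = {f: i for i, f in enumerate(all_features)}
        counts_arr = np.zeros((len(all_features), k_ref))
        included_arr = np.zeros(len(all_features), dtype=int)
        mismatches = 0

        streams = np.random.SeedSequence(seed).spawn(self.n_replicates)
        for i in range(self.n_replicates):
            rep = self._replicate(i, np.random.default_rng(streams[i]))
            if rep is None:
                continue
            if rep.k != k_ref:
                mismatches += 1
            mapping = _match_to_reference(rep, ref_labels, k_ref)
            rows = np.fromiter((fidx[f] for f in rep.feature_ids), dtype=int)
            cols = np.fromiter((mapping[int(l)] - 1 for l in rep.labels), dtype=int)
            np.add.at(counts_arr, (rows, cols), 1.0)
            included_arr[rows] += 1

        counts = pd.DataFrame(counts_arr, index=all_features, columns=cluster_cols)
        included = pd.Series(included_arr, index=all_features, dtype=int)
        ever = included[included > 0].index
        support = counts.loc[ever] / self.n_replicates
        # argmax with deterministic tie-break: lowest cluster index wins
        assignment = support.idxmax(axis=1)
        return SuccessionResults(
            support=support,
            assignment=assignment,
            n_replicates=self.n_replicates,
            n_replicates_included=included.loc[ever],
            reference_k=k_ref,
            reference_labels=ref_labels,
            silhouette_profile=profile,
            k_mismatch_count=mismatches,
            seed=seed,
        )


def cluster_support(
    leaf_table: FeatureTable,
    n_replicates: int = 1000,
    depth: int = 912,
    min_total: int = 25,
    seed: int | None = None,
    k: int | None = None,
) -> SuccessionResults:
    """Convenience wrapper: ``SuccessionClustering(...).fit(seed)``."""
    return SuccessionClustering(
        leaf_table, n_replicates=n_replicates, depth=depth, min_total=min_total, k=k
    ).fit(seed=seed)


# ---------------------------------------------------------------------------
# cluster views over time
# ---------------------------------------------------------------------------

def cluster_timeseries(
    table: FeatureTable,
    results: SuccessionResults,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Per sample, the summed relative abundance of each cluster.

    Features never retained by any replicate (hence unassigned) are pooled
    into an ``other`` category; per sample, cluster fractions plus ``other``
    sum to 1.
    """
    rel = table.relative_abundance()
    meta = metadata.df.loc[[s for s in table.sample_ids if s in set(metadata.sample_ids)]]
    assigned = results.assignment
    members = {
        c: [f for f in assigned.index[assigned == c] if f in rel.index]
        for c in results.cluster_labels
    }
    rows = []
    for s in rel.columns:
        total = 0.0
        for c in results.cluster_labels:
            frac = float(rel.loc[members[c], s].sum()) if members[c] else 0.0
            total += frac
            rows.append((s, c, frac))
        rows.append((s, "other", 1.0 - total))
    out = pd.DataFrame(rows, columns=["sample_id", "cluster", "rel_abundance"])
    out = out.merge(
        meta[["tree_id", "days_since_emergence", "land_use"]],
        left_on="sample_id",
        right_index=True,
        how="left",
    )
    return out


def name_clusters(
    table: FeatureTable,
    results: SuccessionResults,
    metadata: SampleMetadata,
) -> dict[str, str]:
    """Post-hoc temporal naming of clusters.

    The cluster with the highest overall mean relative abundance is
    ``general``; the remaining clusters are ranked by abundance-weighted mean
    time and named ``early`` / ``middle`` / ``late`` (or ``stage_i`` when
    k != 4).
    """
    ts = cluster_timeseries(table, results, metadata)
    ts = ts[ts["cluster"] != "other"].dropna(subset=["days_since_emergence"])
    mean_ab = ts.groupby("cluster", observed=True)["rel_abundance"].mean()
    general = mean_ab.idxmax()
    rest = [c for c in results.cluster_labels if c != general]

    def weighted_time(c: str) -> float:
        sub = ts[ts["cluster"] == c]
        w = sub["rel_abundance"].to_numpy()
        t = sub["days_since_emergence"].to_numpy(dtype=float)
        return float((w * t).sum() / w.sum()) if w.sum() > 0 else np.inf

    rest.sort(key=weighted_time)
    names = {general: "general"}
    stage_names = (
        ["early", "middle", "late"]
        if len(rest) == 3
        else [f"stage_{i+1}" for i in range(len(rest))]
    )
    for c, nm in zip(rest, stage_names):
        names[c] = nm
    return names


def plot_cluster_timeseries(timeseries: pd.DataFrame, ax=None):
    """Cluster relative abundances over days since emergence (one line per
    cluster, tree-level points)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c, sub in timeseries[timeseries["cluster"] != "other"].groupby("cluster"):
        sub = sub.dropna(subset=["days_since_emergence"])
        means = sub.groupby("days_since_emergence")["rel_abundance"].mean()
        ax.plot(means.index, means.values, marker="o", label=c)
        ax.scatter(sub["days_since_emergence"], sub["rel_abundance"], s=8, alpha=0.3)
    ax.set_xlabel("days since leaf emergence")
    ax.set_ylabel("cluster relative abundance")
    ax.legend(fontsize="small")
    return ax
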