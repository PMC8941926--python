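"""Presence-based ASV overlap between compartments, ubiquity across trees,
and shared-taxon fractions between groups of samples.

Presence throughout this module uses the decontamination-derived read
threshold: an ASV is present in a sample only when its count strictly
exceeds ``min_reads`` (default 10), and present in a group when present in
at least one of the group's samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .data_model import FeatureTable, SampleMetadata, TaxonomyTable
from .succession import SuccessionResults, cluster_timeseries


def presence_sets(
    table: FeatureTable,
    metadata: SampleMetadata,
    group_by: str,
    min_reads: int = 10,
) -> dict[str, set[str]]:
    """Feature sets per level of ``group_by`` (presence = count > min_reads
    in at least one sample of the group)."""
    meta = metadata.nonblank()
    meta = meta.loc[[s for s in meta.index if s in set(table.sample_ids)]]
    out: dict[str, set[str]] = {}
    for level, sub in meta.groupby(group_by, observed=True):
        counts = table.counts[list(sub.index)]
        present = (counts > min_reads).any(axis=1)
        out[str(level)] = set(present.index[present])
    return out


@dataclass
class OverlapResult:
    """Per leaf cluster: where its ASVs also occur, and how much of the leaf
    community they explain inside the cluster's time frame."""

    table: pd.DataFrame
    # columns: cluster, category, n_features, fraction_of_cluster
    abundance_share: pd.Series  # per cluster: mean leaf rel. abundance of shared ASVs
    time_frames: dict[str, tuple[float, float]]


def default_time_frames(
    table: FeatureTable,
    results: SuccessionResults,
    metadata: SampleMetadata,
) -> dict[str, tuple[float, float]]:
    """Per cluster, the maximal contiguous day window (containing the peak)
    where the cluster's mean relative abundance exceeds its median across
    time points."""
    ts = cluster_timeseries(table, results, metadata)
    ts = ts[ts["cluster"] != "other"].dropna(subset=["days_since_emergence"])
    frames = {}
    for c, sub in ts.groupby("cluster", observed=True):
        means = sub.groupby("days_since_emergence")["rel_abundance"].mean().sort_index()
        med = means.median()
        above = means > med
        days = means.index.to_numpy(dtype=float)
        if not above.any():
            frames[c] = (float(days[0]), float(days[-1]))
            continue
        peak = int(np.argmax(means.to_numpy()))
        lo = peak
        while lo > 0 and above.iloc[lo - 1]:
            lo -= 1
        hi = peak
        while hi < len(days) - 1 and above.iloc[hi + 1]:
            hi += 1
        frames[c] = (float(days[lo]), float(days[hi]))
    return frames


def cluster_compartment_overlap(
    results: SuccessionResults,
    leaf_table: FeatureTable,
    other_sets: Mapping[str, set[str]],
    metadata: SampleMetadata,
    time_frames: Mapping[str, tuple[float, float]] | None = None,
) -> OverlapResult:
    """Decompose each leaf cluster's ASVs by where else they occur.

    Categories are mutually exclusive: one per single other compartment,
    ``combination`` for ASVs found in more than one other compartment, and
    ``leaf_only``. The shared fraction of a cluster is everything except
    ``leaf_only``. ``abundance_share`` is the mean relative abundance the
    shared ASVs hold in leaf samples inside the cluster's time frame.
    """
    if time_frames is None:
        time_frames = default_time_frames(leaf_table, results, metadata)
    rel = leaf_table.relative_abundance()
    meta = metadata.df.loc[[s for s in leaf_table.sample_ids if s in set(metadata.sample_ids)]]
    compartments = sorted(other_sets)
    rows = []
    shares = {}
    for c in results.cluster_labels:
        members = list(results.assignment.index[results.assignment == c])
        if not members:
            raise ValueError(f"cluster {c} has no assigned features")
        cats: dict[str, set[str]] = {comp: set() for comp in compartments}
        cats["combination"] = set()
        cats["leaf_only"] = set()
        for f in members:
            found = [comp for comp in compartments if f in other_sets[comp]]
            if not found:
                cats["leaf_only"].add(f)
            elif len(found) == 1:
                cats[found[0]].add(f)
            else:
                cats["combination"].add(f)
        for cat, feats in cats.items():
            rows.append((c, cat, len(feats), len(feats) / len(members)))
        shared = [f for f in members if f not in cats["leaf_only"]]
        lo, hi = time_frames.get(c, (-np.inf, np.inf))
        in_frame = meta.index[
            (meta["days_since_emergence"] >= lo) & (meta["days_since_emergence"] <= hi)
        ]
        in_frame = [s for s in in_frame if s in rel.columns]
        shared_in = [f for f in shared if f in rel.index]
        shares[c] = (
            float(rel.loc[shared_in, in_frame].sum(axis=0).mean())
            if shared_in and len(in_frame)
            else 0.0
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "category", "n_features", "fraction_of_cluster"]
    )
    return OverlapResult(
        table=table,
        abundance_share=pd.Series(shares, name="abundance_share"),
        time_frames=dict(time_frames),
    )


def shared_fraction_of_cluster(result: OverlapResult, cluster: str) -> float:
    """Fraction of a cluster's ASVs found in at least one other compartment."""
    t = result.table
    sub = t[(t["cluster"] == cluster) & (t["category"] != "leaf_only")]
    return float(sub["fraction_of_cluster"].sum())


@dataclass
class UbiquityResult:
    """Per assigned ASV: in how many trees (within scope) it is present."""

    counts: pd.Series  # index feature_id, values int
    cluster: pd.Series  # feature_id -> cluster label
    n_trees: int

    def mean_by_cluster(self) -> pd.Series:
        return self.counts.groupby(self.cluster).mean()


def ubiquity(
    results: SuccessionResults,
    table: FeatureTable,
    metadata: SampleMetadata,
    scope: str = "one_city",
    city: str | None = None,
    min_reads: int = 10,
) -> UbiquityResult:
    """Number of distinct trees in which each assigned ASV is present.

    ``scope="one_city"`` restricts to one city's trees (the first city in
    the metadata unless ``city`` is given); ``scope="both_cities"`` counts
    over all trees.
    """
    meta = metadata.nonblank()
    meta = meta.loc[[s for s in meta.index if s in set(table.sample_ids)]]
    if scope == "one_city":
        if city is None:
            city = sorted(meta["city"].unique())[0]
        meta = meta[meta["city"] == city]
    elif scope != "both_cities":
        raise ValueError("scope must be 'one_city' or 'both_cities'")
    trees = meta["tree_id"].unique()
    feats = list(results.assignment.index)
    feats = [f for f in feats if f in set(table.feature_ids)]
    counts = pd.Series(0, index=feats, dtype=int)
    for tree in trees:
        sids = list(meta.index[meta["tree_id"] == tree])
        present = (table.counts.loc[feats, sids] > min_reads).any(axis=1)
        counts += present.astype(int)
    return UbiquityResult(
        counts=counts,
        cluster=results.assignment.loc[feats],
        n_trees=len(trees),
    )


def shared_fraction(
    table_a: FeatureTable,
    table_b: FeatureTable,
    level: str = "asv",
    taxonomy: TaxonomyTable | None = None,
    min_reads: int = 0,
) -> dict[str, float]:
    """Fraction of features (or genera) shared between two sample groups.

    Returns both conventions: ``fraction_of_union`` (|A∩B| / |A∪B|, Jaccard)
    and ``fraction_of_total`` (identical here — the union *is* the total set
    of observed labels; kept as an explicit alias for reporting).
    """
    def labels(t: FeatureTable) -> set[str]:
        present = (t.counts > min_reads).any(axis=1)
        feats = set(present.index[present])
        if level == "genus":
            if taxonomy is None:
                raise ValueError("genus-level sharing requires a taxonomy")
            lab = taxonomy.label_at_rank("genus")
            return {lab[f] for f in feats}
        if level != "asv":
            raise ValueError("level must be 'asv' or 'genus'")
        return feats

    a, b = labels(table_a), labels(table_b)
    union = a | b
    inter = a & b
    frac = len(inter) / len(union) if union else 0.0
    return {"fraction_of_union": frac, "fraction_of_total": frac,
            "n_shared": len(inter), "n_total": len(union)}
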