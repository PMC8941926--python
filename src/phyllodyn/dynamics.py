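"""Community dynamics along the leaf-emergence chronosequence.

Two dissimilarity series summarise how a compartment's communities move:

* **consecutive** — Bray-Curtis between the same tree's samples at adjacent
  sampled time points (the community *change rate*; a decreasing series
  means the community is stabilising);
* **within_timepoint** — Bray-Curtis between different trees sharing a time
  point (between-tree heterogeneity; a decreasing series would mean trees
  converge on a common composition).

Monotone trend over days since leaf emergence is tested with Kendall's
tau-b rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .betadiv import bray_curtis
from .data_model import FeatureTable, SampleMetadata


@dataclass
class DissimilaritySeries:
    """Long-format record set: one Bray-Curtis value per row."""

    records: pd.DataFrame  # columns: tree_id, compartment, time_days, dissimilarity, kind
    kind: str  # "consecutive" | "within_timepoint"

    @property
    def time(self) -> np.ndarray:
        return self.records["time_days"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.records["dissimilarity"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class TrendResult:
    tau: float
    p_value: float
    n: int


def _compartment_samples(
    metadata: SampleMetadata, compartment: str, table: FeatureTable
) -> pd.DataFrame:
    meta = metadata.nonblank()
    meta = meta[meta["compartment"] == compartment]
    meta = meta.loc[[s for s in meta.index if s in set(table.sample_ids)]]
    if meta.empty:
        raise ValueError(f"no samples for compartment {compartment!r}")
    return meta


def consecutive_dissimilarity(
    table: FeatureTable,
    metadata: SampleMetadata,
    compartment: str,
    relative: bool = True,
    disjoint: bool = False,
) -> DissimilaritySeries:
    """Bray-Curtis between adjacent time points of the same tree.

    Each record is timestamped at the *later* time point of the pair (the
    change is realised by then). Time points lost to depth filtering are
    simply skipped — adjacency is taken over the retained time points.

    With ``disjoint=True`` only every other adjacent pair is kept
    ((t1,t2), (t3,t4), …), so no two records share a sample. The full
    overlapping series is the conventional change-rate statistic but its
    records are serially dependent (adjacent records share the middle
    sample), which makes trend tests on it slightly anticonservative under
    the null; the disjoint series is exchangeable under the null and is
    what the type-I calibration uses.
    """
    meta = _compartment_samples(metadata, compartment, table)
    rows = []
    for tree, sub in meta.groupby("tree_id", observed=True):
        sub = sub.sort_values("days_since_emergence")
        sids = list(sub.index)
        days = sub["days_since_emergence"].to_numpy(dtype=float)
        step = 2 if disjoint else 1
        for i in range(0, len(sids) - 1, step):
            pair = table.select_samples([sids[i], sids[i + 1]])
            d = float(bray_curtis(pair, relative=relative).data[0, 1])
            rows.append((tree, compartment, days[i + 1], d, "consecutive"))
    rec = pd.DataFrame(
        rows, columns=["tree_id", "compartment", "time_days", "dissimilarity", "kind"]
    )
    return DissimilaritySeries(rec, "consecutive")


def within_timepoint_dissimilarity(
    table: FeatureTable,
    metadata: SampleMetadata,
    compartment: str,
    relative: bool = True,
) -> DissimilaritySeries:
    """All pairwise Bray-Curtis values among trees sharing a time point."""
    meta = _compartment_samples(metadata, compartment, table)
    rows = []
    for day, sub in meta.groupby("days_since_emergence", observed=True):
        sids = list(sub.index)
        if len(sids) < 2:
            continue
        dm = bray_curtis(table.select_samples(sids), relative=relative)
        for i, j in combinations(range(len(sids)), 2):
            pair_label = f"{sub['tree_id'].iloc[i]}|{sub['tree_id'].iloc[j]}"
            rows.append((pair_label, compartment, float(day), float(dm.data[i, j]),
                         "within_timepoint"))
    rec = pd.DataFrame(
        rows, columns=["tree_id", "compartment", "time_days", "dissimilarity", "kind"]
    )
    return DissimilaritySeries(rec, "within_timepoint")


def kendall_trend(series: DissimilaritySeries) -> TrendResult:
    """Kendall tau-b trend of dissimilarity against time.

    Exact p-value for small untied samples, normal approximation with tie
    correction otherwise (scipy's "auto" policy).
    """
    x, y = series.time, series.values
    if len(x) < 3:
        raise ValueError(f"need at least 3 records, got {len(x)}")
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise ValueError("constant series: Kendall tau is undefined")
    res = stats.kendalltau(x, y)
    return TrendResult(tau=float(res.statistic), p_value=float(res.pvalue), n=len(x))
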