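"""Post-denoising table filters applied before any community analysis.

Three filters, applied in this order by :func:`preprocess`:

1. drop non-bacterial features (chloroplast, mitochondria, Archaea,
   unassigned-domain),
2. drop features whose representative-sequence length falls outside a batch
   specific window (V4 amplicons: 251–256 bp for one library preparation,
   234–265 bp for the other),
3. drop samples with fewer than 200 reads (strictly fewer — a 200-read sample
   is kept).

Boundary semantics are strict throughout: "less than" / "more than" remove,
the boundary value survives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import pandas as pd

from .data_model import FeatureTable, TaxonomyTable

#: Lineage patterns treated as non-bacterial (matched case-insensitively
#: against every rank name and the domain).
DEFAULT_NONBACTERIAL_PATTERNS: tuple[str, ...] = (
    r"chloroplast",
    r"mitochondri",
    r"^archaea$",
    r"^eukaryota$",
)


@dataclass(frozen=True)
class FilterReport:
    """What a single filter removed."""

    n_features_removed: int
    n_samples_removed: int
    reads_removed_fraction: float
    rule: str

    def __post_init__(self):
        if not 0.0 <= self.reads_removed_fraction <= 1.0:
            raise ValueError("reads_removed_fraction must lie in [0, 1]")
        if self.n_features_removed < 0 or self.n_samples_removed < 0:
            raise ValueError("removal counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_features_removed": self.n_features_removed,
            "n_samples_removed": self.n_samples_removed,
            "reads_removed_fraction": self.reads_removed_fraction,
        }


def _report(before: FeatureTable, after: FeatureTable, rule: str) -> FilterReport:
    tot = before.total()
    removed = tot - after.total()
    return FilterReport(
        n_features_removed=before.shape[0] - after.shape[0],
        n_samples_removed=before.shape[1] - after.shape[1],
        reads_removed_fraction=(removed / tot) if tot else 0.0,
        rule=rule,
    )


def filter_nonbacterial(
    table: FeatureTable,
    taxonomy: TaxonomyTable,
    patterns: Sequence[str] = DEFAULT_NONBACTERIAL_PATTERNS,
) -> tuple[FeatureTable, FilterReport]:
    """Remove chloroplast/mitochondrial/archaeal/unassigned-domain features."""
    taxonomy.check_covers(table)
    regexes = [re.compile(p, re.IGNORECASE) for p in patterns]
    doomed = []
    for fid in table.feature_ids:
        lineage = taxonomy.df.loc[fid]
        if any(rx.search(str(v)) for v in lineage for rx in regexes):
            doomed.append(fid)
    out = table.drop_features(doomed)
    return out, _report(table, out, "nonbacterial")


def filter_by_length(
    table: FeatureTable,
    lengths: Mapping[str, int] | pd.Series,
    min_bp: int,
    max_bp: int,
) -> tuple[FeatureTable, FilterReport]:
    """Keep features with ``min_bp <= length <= max_bp`` (inclusive window)."""
    lengths = pd.Series(lengths)
    missing = set(table.feature_ids) - set(lengths.index)
    if missing:
        raise KeyError(f"missing sequence length for feature(s): {sorted(missing)[:10]}")
    keep = [f for f in table.feature_ids if min_bp <= int(lengths[f]) <= max_bp]
    out = table.select_features(keep)
    return out, _report(table, out, f"length[{min_bp},{max_bp}]")


def filter_low_depth_samples(
    table: FeatureTable, min_reads: int = 200
) -> tuple[FeatureTable, FilterReport]:
    """Drop samples whose total read count is strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= min_reads]
    if not keep:
        raise ValueError(
            f"depth filter at {min_reads} reads would remove every sample"
        )
    out = table.select_samples(keep)
    return out, _report(table, out, f"min_depth[{min_reads}]")


def preprocess(
    table: FeatureTable,
    taxonomy: TaxonomyTable,
    lengths: Mapping[str, int] | pd.Series | None = None,
    min_bp: int | None = None,
    max_bp: int | None = None,
    min_reads: int = 200,
    nonbacterial_patterns: Sequence[str] = DEFAULT_NONBACTERIAL_PATTERNS,
) -> tuple[FeatureTable, list[FilterReport]]:
    """Run the standard filter chain: non-bacterial → length → sample depth.

    The depth filter runs last so that depth loss caused by chloroplast
    removal (severe in leaf and bud samples) is reflected in the 200-read cut.
    """
    reports = []
    table, rep = filter_nonbacterial(table, taxonomy, nonbacterial_patterns)
    reports.append(rep)
    if lengths is not None and min_bp is not None and max_bp is not None:
        table, rep = filter_by_length(table, lengths, min_bp, max_bp)
        reports.append(rep)
    table, rep = filter_low_depth_samples(table, min_reads)
    reports.append(rep)
    return table, reports
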