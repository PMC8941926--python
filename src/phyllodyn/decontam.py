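"""Blank-based contaminant classification and the presence threshold.

Kit negative controls ("blanks") capture two kinds of contamination:

* **external** contaminants — DNA introduced by reagents or handling
  (typical kit genera, human-associated taxa); these are removed from the
  data set entirely;
* **cross** contaminants — abundant genuine sample taxa that leaked into the
  blanks during library preparation; these stay in the data set.

Because published blank curation is usually a manual taxon-by-taxon
judgement, this module encodes it as explicit rules: a dominance rule
(features whose mean relative abundance across real samples sits in a top
quantile are cross-contamination), a kit/human-associated genus list and
user-supplied whitelist/blacklist overrides. Features no rule can place
default to *external* (the conservative call) and are flagged for review.

The distribution of external-contaminant counts in real samples then yields
a per-sample presence threshold: the smallest read count ``t`` such that
requiring ``count > t`` for presence discards at least a target fraction
(default one half) of contaminant presence instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .data_model import FeatureTable, SampleMetadata, TaxonomyTable
from .preprocess import FilterReport, _report

#: Genera repeatedly reported as DNA-extraction-kit or human-skin/oral
#: contaminants in the negative-control literature.
DEFAULT_KIT_CONTAMINANT_GENERA: frozenset[str] = frozenset(
    {
        "Ralstonia",
        "Cupriavidus",
        "Delftia",
        "Burkholderia",
        "Bradyrhizobium",
        "Herbaspirillum",
        "Stenotrophomonas",
        "Escherichia",
        "Shigella",
        "Corynebacterium",
        "Cutibacterium",
        "Propionibacterium",
        "Staphylococcus",
        "Streptococcus",
        "Enterococcus",
        "Lactobacillus",
        "Veillonella",
        "Prevotella",
        "Haemophilus",
        "Neisseria",
    }
)


@dataclass(frozen=True)
class ContaminantRules:
    """Configurable rule set for classifying blank-occurring features."""

    dominance_quantile: float = 0.9  # top decile of mean relative abundance
    kit_genera: frozenset[str] = DEFAULT_KIT_CONTAMINANT_GENERA
    whitelist: frozenset[str] = field(default_factory=frozenset)  # force cross
    blacklist: frozenset[str] = field(default_factory=frozenset)  # force external


@dataclass(frozen=True)
class ContaminantCall:
    feature_id: str
    call: str  # "external" | "cross" | "clean"
    evidence: str
    needs_review: bool = False


def classify_blank_features(
    table: FeatureTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable,
    rules: ContaminantRules = ContaminantRules(),
) -> list[ContaminantCall]:
    """Call every blank-occurring feature external or cross.

    Rule precedence per feature found in any blank:

    1. whitelist → cross;  blacklist → external  (user overrides)
    2. dominance: mean relative abundance across non-blank samples in the
       top ``1 - dominance_quantile`` tail → cross (a genuine, abundant
       sample taxon that leaked into the blanks)
    3. genus on the kit/human-contaminant list → external
    4. otherwise → external, flagged for review.

    Features never seen in a blank are clean.
    """
    blanks = metadata.blank_ids()
    blanks = [b for b in blanks if b in set(table.sample_ids)]
    if not blanks:
        raise ValueError(
            "no blank samples in the table; to proceed without decontamination, "
            "skip this step explicitly"
        )
    taxonomy.check_covers(table)
    sample_ids = [s for s in table.sample_ids if s not in set(blanks)]
    blank_occurring = [
        f for f in table.feature_ids if table.counts.loc[f, blanks].sum() > 0
    ]
    rel = table.select_samples(sample_ids).relative_abundance()
    mean_rel = rel.mean(axis=1)
    cutoff = float(mean_rel.quantile(rules.dominance_quantile))

    calls: list[ContaminantCall] = []
    for fid in table.feature_ids:
        if fid not in set(blank_occurring):
            calls.append(ContaminantCall(fid, "clean", "absent from blanks"))
            continue
        genus = taxonomy.df.loc[fid, "genus"]
        if fid in rules.whitelist or genus in rules.whitelist:
            calls.append(ContaminantCall(fid, "cross", "whitelist"))
        elif fid in rules.blacklist or genus in rules.blacklist:
            calls.append(ContaminantCall(fid, "external", "blacklist"))
        elif float(mean_rel.get(fid, 0.0)) > cutoff:
            calls.append(
                ContaminantCall(
                    fid,
                    "cross",
                    f"dominance: mean rel. abundance {mean_rel[fid]:.2e} > "
                    f"q{rules.dominance_quantile:g} cutoff {cutoff:.2e}",
                )
            )
        elif genus in rules.kit_genera:
            calls.append(ContaminantCall(fid, "external", f"kit-contaminant genus {genus}"))
        else:
            calls.append(
                ContaminantCall(fid, "external", "no rule matched; conservative default",
                                needs_review=True)
            )
    return calls


def remove_external(
    table: FeatureTable,
    calls: Sequence[ContaminantCall],
    metadata: SampleMetadata | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Drop external-called features entirely, then drop the blank samples."""
    external = {c.feature_id for c in calls if c.call == "external"}
    out = table.drop_features(external)
    rep = _report(table, out, "external_contaminants")
    if metadata is not None:
        out = out.drop_samples(metadata.blank_ids())
    return out, FilterReport(
        n_features_removed=rep.n_features_removed,
        n_samples_removed=table.shape[1] - out.shape[1],
        reads_removed_fraction=rep.reads_removed_fraction,
        rule=rep.rule,
    )


def presence_threshold(
    table: FeatureTable,
    contaminant_ids: Iterable[str],
    target_fraction: float = 0.5,
) -> int:
    """Smallest integer ``t`` discarding ≥ ``target_fraction`` of contaminant
    presence instances when presence requires ``count > t``.

    A presence instance is a (contaminant feature, sample) pair with a
    nonzero count; the returned threshold is the smallest ``t`` for which the
    fraction of instances with ``count <= t`` reaches ``target_fraction``.
    """
    ids = list(contaminant_ids)
    if not ids:
        raise ValueError("contaminant_ids must be non-empty")
    missing = set(ids) - set(table.feature_ids)
    if missing:
        raise KeyError(f"contaminant feature(s) not in table: {sorted(missing)[:10]}")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    counts = table.counts.loc[ids].to_numpy().ravel()
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("contaminant features have no presence instances")
    if target_fraction == 0.0:
        return 0
    counts.sort()
    # fraction of instances <= t first reaches target at the
    # ceil(target * n)-th order statistic
    k = int(np.ceil(target_fraction * counts.size))
    return int(counts[k - 1])
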