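"""Compartment-associated taxa: core genera and indicator analysis.

A genus is a *core* genus of a compartment when it is present — represented
by strictly more than a read threshold (default 10, derived from the blank
contaminant distribution) — in strictly more than a prevalence threshold
(default 95%) of that compartment's samples.

Indicator analysis scores every genus against every compartment or pair of
compartments with the group-size-corrected indicator value

.. math:: \\mathrm{IndVal.g} = \\sqrt{A \\cdot B}

where *A* (specificity) is the genus's mean abundance in the target group
divided by the sum of its per-compartment mean abundances, and *B*
(fidelity) is the fraction of target-group samples in which the genus
occurs. Significance is assessed by permuting compartment labels.

Because the indicator statistic needs non-negative abundances while the
centred-log-ratio (CLR) transform produces negatives, the CLR mode shifts
each genus by its global minimum before scoring (so its smallest value
becomes zero); a raw relative-abundance mode is available as the
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import FeatureTable, SampleMetadata


@dataclass
class CoreTaxaResult:
    """Per-compartment core genera with prevalence and mean relative abundance."""

    table: pd.DataFrame  # columns: compartment, genus, prevalence, mean_rel_abundance, core

    def core_genera(self, compartment: str) -> list[str]:
        t = self.table
        return sorted(t.loc[(t["compartment"] == compartment) & t["core"], "genus"])


def core_taxa(
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    presence_min_reads: int = 10,
    prevalence_threshold: float = 0.95,
) -> CoreTaxaResult:
    """Determine the core genera of each compartment.

    Presence requires ``count > presence_min_reads``; core status requires
    ``prevalence > prevalence_threshold`` (both strict).
    """
    meta = metadata.nonblank()
    meta = meta.loc[[s for s in meta.index if s in set(genus_table.sample_ids)]]
    if meta.empty:
        raise ValueError("no samples with metadata to determine core taxa from")
    rel = genus_table.relative_abundance()
    rows = []
    for comp, sub in meta.groupby("compartment", observed=True):
        sids = list(sub.index)
        if not sids:
            raise ValueError(f"compartment {comp!r} has no samples")
        counts = genus_table.counts[sids]
        present = counts > presence_min_reads
        prevalence = present.sum(axis=1) / len(sids)
        mean_rel = rel[sids].mean(axis=1)
        for genus in genus_table.feature_ids:
            rows.append(
                (
                    comp,
                    genus,
                    float(prevalence[genus]),
                    float(mean_rel[genus]),
                    bool(prevalence[genus] > prevalence_threshold),
                )
            )
    table = pd.DataFrame(
        rows, columns=["compartment", "genus", "prevalence", "mean_rel_abundance", "core"]
    )
    return CoreTaxaResult(table)


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred-log-ratio transform per sample.

    ``clr(x_i) = log(x_i + pseudocount) - mean_j log(x_j + pseudocount)``;
    each sample's transformed values sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.feature_ids, columns=table.sample_ids)


@dataclass
class IndicatorResult:
    """IndVal.g statistics for every genus × group-combination."""

    table: pd.DataFrame  # genus, groups, A, B, stat, p_value, p_adjusted
    n_permutations: int
    seed: object

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Best combination per genus, filtered at adjusted ``alpha``."""
        t = self.table
        best = t.loc[t.groupby("genus", observed=True)["stat"].idxmax()]
        return best[best["p_adjusted"] <= alpha].reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _indval_matrix(
    values: np.ndarray, codes: np.ndarray, n_groups: int, combos: list[tuple[int, ...]]
) -> np.ndarray:
    """IndVal.g statistic for every feature (rows) × combination (cols)."""
    group_means = np.stack(
        [values[:, codes == g].mean(axis=1) for g in range(n_groups)], axis=1
    )
    occur = values > 0
    denom = group_means.sum(axis=1)
    stats = np.zeros((values.shape[0], len(combos)))
    for j, combo in enumerate(combos):
        # group-size-corrected specificity: per-group means (not pooled
        # sample means) enter both numerator and denominator
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(
                denom > 0,
                group_means[:, list(combo)].sum(axis=1) / denom,
                0.0,
            )
        in_combo = np.isin(codes, combo)
        b = occur[:, in_combo].mean(axis=1)
        stats[:, j] = np.sqrt(np.clip(a, 0, 1) * b)
    return stats


def indicator_analysis(
    values: pd.DataFrame | FeatureTable,
    metadata: SampleMetadata,
    grouping: str = "compartment",
    max_order: int = 2,
    n_permutations: int = 999,
    seed: int | None = None,
    final_timepoint_only: bool = True,
    mode: str = "clr_shifted",
    pseudocount: float = 1.0,
) -> IndicatorResult:
    """IndVal.g indicator analysis of genera against compartment groups.

    Parameters
    ----------
    values
        Genus-level FeatureTable, or a precomputed non-negative value matrix
        (features × samples DataFrame).
    final_timepoint_only
        Restrict to each city's last sampling time point (avoids temporal
        pseudo-replication of the same trees).
    mode
        ``"clr_shifted"`` (CLR then shift each genus by its global minimum)
        or ``"relative"`` (plain relative abundances).
    """
    if isinstance(values, FeatureTable):
        if mode == "clr_shifted":
            mat = clr_transform(values, pseudocount)
            mat = mat.sub(mat.min(axis=1), axis=0)
        elif mode == "relative":
            mat = values.relative_abundance()
        else:
            raise ValueError(f"unknown mode {mode!r}")
    else:
        mat = pd.DataFrame(values)
        if (mat.to_numpy() < 0).any():
            raise ValueError("value matrix must be non-negative")

    meta = metadata.nonblank()
    meta = meta.loc[[s for s in meta.index if s in set(mat.columns)]]
    if final_timepoint_only:
        keep = []
        for _, sub in meta.groupby("city", observed=True):
            last = sub["days_since_emergence"].max()
            keep.extend(sub.index[sub["days_since_emergence"] == last])
        meta = meta.loc[keep]
    mat = mat[list(meta.index)]

    codes, uniques = pd.factorize(meta[grouping].astype(str))
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError(
            f"indicator analysis needs >= 2 groups, found {list(uniques)}"
        )
    sizes = np.bincount(codes, minlength=n_groups)
    if (sizes < 2).any():
        small = [uniques[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with < 2 samples: {small}")
    combos: list[tuple[int, ...]] = []
    for order in range(1, min(max_order, n_groups - 1) + 1):
        combos.extend(combinations(range(n_groups), order))

    vals = mat.to_numpy(dtype=float)
    obs = _indval_matrix(vals, codes, n_groups, combos)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = _indval_matrix(vals, codes[rng.permutation(codes.size)], n_groups, combos)
        exceed += perm >= obs - 1e-12
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    group_means = np.stack(
        [vals[:, codes == g].mean(axis=1) for g in range(n_groups)], axis=1
    )
    denom = group_means.sum(axis=1)
    rows = []
    for i, genus in enumerate(mat.index):
        for j, combo in enumerate(combos):
            with np.errstate(invalid="ignore", divide="ignore"):
                a = group_means[i, list(combo)].sum() / denom[i] if denom[i] > 0 else 0.0
            b = (vals[i, np.isin(codes, combo)] > 0).mean()
            rows.append(
                (
                    genus,
                    "+".join(uniques[g] for g in combo),
                    float(np.clip(a, 0, 1)),
                    float(b),
                    float(obs[i, j]),
                    float(pvals[i, j]),
                )
            )
    table = pd.DataFrame(rows, columns=["genus", "groups", "A", "B", "stat", "p_value"])
    table["p_adjusted"] = _bh_adjust(table["p_value"].to_numpy())
    return IndicatorResult(table, n_permutations, seed)
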