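"""Core containers for amplicon community data.

Three tabular objects travel through every analysis step:

* :class:`FeatureTable` — an ASV (or genus) × sample matrix of non-negative
  integer read counts,
* :class:`TaxonomyTable` — a six-rank lineage (domain … genus) per feature,
* :class:`SampleMetadata` — per-sample study factors (city, tree individual,
  phyllosphere compartment, sampling date, days since leaf emergence, land
  use, blank flag).

All three are thin, validated wrappers around :class:`pandas.DataFrame`; the
underlying frame is always reachable as ``.df`` (or ``.counts`` for the
feature table) so the usual pandas idioms keep working.
"""

from __future__ import annotations

import datetime as _dt
import json
from collections.abc import Iterable, Mapping
from typing import Literal

import numpy as np
import pandas as pd

RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")
#: Explicit marker for a rank that could not be assigned. Never an empty string.
UNKNOWN: str = "__unknown__"
COMPARTMENTS: tuple[str, ...] = ("leaf", "bud", "branch", "trunk")
LAND_USES: tuple[str, ...] = ("park", "street")

#: Default leaf-emergence dates per city (overridable wherever dates are read).
DEFAULT_EMERGENCE_DATES: dict[str, _dt.date] = {
    "Antwerp": _dt.date(2018, 4, 17),
    "Milan": _dt.date(2018, 4, 11),
}


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dup}")


class FeatureTable:
    """Feature × sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with feature ids as index and sample ids as columns.
        Values must be non-negative integers (integer dtype, or floats that
        are exactly integral — these are cast).
    """

    def __init__(self, counts: pd.DataFrame, *, validate: bool = True):
        counts = pd.DataFrame(counts)
        if validate:
            _check_unique(counts.index, "feature")
            _check_unique(counts.columns, "sample")
            arr = counts.to_numpy()
            if arr.size:
                if not np.issubdtype(arr.dtype, np.integer):
                    frac = np.mod(arr.astype(float), 1.0)
                    bad = np.argwhere(frac != 0)
                    if bad.size:
                        i, j = bad[0]
                        raise ValidationError(
                            "non-integer count at feature "
                            f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
                        )
                neg = np.argwhere(arr.astype(float) < 0)
                if neg.size:
                    i, j = neg[0]
                    raise ValidationError(
                        f"negative count at feature {counts.index[i]!r}, "
                        f"sample {counts.columns[j]!r}"
                    )
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    # -- basic introspection -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def feature_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1).

        Raises on all-zero samples, which carry no compositional information.
        """
        sums = self.sample_sums()
        zero = sums[sums == 0]
        if len(zero):
            raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
        return self.counts / sums

    # -- subsetting ----------------------------------------------------------
    def select_samples(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        missing = set(ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return FeatureTable(self.counts.loc[:, ids], validate=False)

    def select_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        missing = set(ids) - set(self.counts.index)
        if missing:
            raise KeyError(f"unknown feature id(s): {sorted(missing)}")
        return FeatureTable(self.counts.loc[ids], validate=False)

    def drop_features(self, ids: Iterable[str]) -> "FeatureTable":
        keep = [f for f in self.counts.index if f not in set(ids)]
        return FeatureTable(self.counts.loc[keep], validate=False)

    def drop_samples(self, ids: Iterable[str]) -> "FeatureTable":
        keep = [s for s in self.counts.columns if s not in set(ids)]
        return FeatureTable(self.counts.loc[:, keep], validate=False)

    def drop_empty_features(self) -> "FeatureTable":
        return FeatureTable(self.counts.loc[self.feature_sums() > 0], validate=False)

    # -- equality (useful in round-trip tests) --------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"<FeatureTable {self.shape[0]} features x {self.shape[1]} samples>"

    # -- I/O -------------------------------------------------------------------
    def write(self, path, dialect: Literal["tsv", "biom_dense"] = "tsv") -> None:
        if dialect == "tsv":
            out = self.counts.copy()
            out.index.name = "feature_id"
            out.to_csv(path, sep="\t")
        elif dialect == "biom_dense":
            payload = {
                "format": "dense",
                "rows": self.feature_ids,
                "columns": self.sample_ids,
                "data": self.counts.to_numpy().tolist(),
            }
            with open(path, "w") as fh:
                json.dump(payload, fh)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")

    @classmethod
    def read(cls, path, dialect: Literal["tsv", "biom_dense"] = "tsv") -> "FeatureTable":
        if dialect == "tsv":
            with open(path) as fh:
                header = fh.readline().rstrip("\n").split("\t")
            sample_ids = header[1:]
            if len(sample_ids) != len(set(sample_ids)):
                seen: set[str] = set()
                dup = [s for s in sample_ids if s in seen or seen.add(s)]  # type: ignore[func-returns-value]
                raise ValidationError(f"duplicate sample id(s): {sorted(set(dup))}")
            df = pd.read_csv(path, sep="\t", index_col=0)
            df.columns = sample_ids
            return cls(df)
        if dialect == "biom_dense":
            with open(path) as fh:
                payload = json.load(fh)
            df = pd.DataFrame(
                payload["data"], index=payload["rows"], columns=payload["columns"]
            )
            return cls(df)
        raise ValueError(f"unknown dialect {dialect!r}")


def read_feature_table(path, dialect: Literal["tsv", "biom_dense"] = "tsv") -> FeatureTable:
    """Read a feature table from ``path`` (TSV or dense BIOM-style JSON)."""
    return FeatureTable.read(path, dialect=dialect)


_RANK_SUFFIX = {r: f"_{r[0]}" for r in RANKS}


class TaxonomyTable:
    """Per-feature lineage over the six ranks domain … genus.

    Unknown ranks are stored as the explicit :data:`UNKNOWN` marker; display
    labels for an unknown rank fall back to the nearest known higher rank with
    a rank-initial suffix (an unknown genus in family ``EU289441`` is shown as
    ``EU289441_g``, matching common amplicon reporting practice).
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = pd.DataFrame(df)
        if validate:
            missing = [r for r in RANKS if r not in df.columns]
            if missing:
                raise ValidationError(f"taxonomy missing rank column(s): {missing}")
            _check_unique(df.index, "feature")
            if (df[list(RANKS)].astype(str) == "").any().any():
                raise ValidationError(
                    f"empty-string rank value; use the {UNKNOWN!r} marker"
                )
        self.df = df[list(RANKS)].astype(str)
        self.df.index = self.df.index.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.feature_ids) - set(self.df.index)
        if missing:
            raise ValidationError(
                f"feature(s) missing from taxonomy: {sorted(missing)[:10]}"
            )

    def label_at_rank(self, rank: str) -> pd.Series:
        """Display label per feature at ``rank`` (fallback for unknowns)."""
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
        upto = RANKS[: RANKS.index(rank) + 1]
        labels = []
        for _, row in self.df.iterrows():
            lineage = [row[r] for r in upto]
            if lineage[-1] != UNKNOWN:
                labels.append(lineage[-1])
                continue
            known = [x for x in lineage if x != UNKNOWN]
            base = known[-1] if known else "Unassigned"
            labels.append(base + _RANK_SUFFIX[rank])
        return pd.Series(labels, index=self.df.index)

    def lineage_key(self, rank: str) -> pd.Series:
        """Full lineage string down to ``rank`` (used for aggregation)."""
        upto = list(RANKS[: RANKS.index(rank) + 1])
        return self.df[upto].agg(";".join, axis=1)

    def write(self, path) -> None:
        out = self.df.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTable):
            return NotImplemented
        return self.df.equals(other.df)


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable.read(path)


_META_COLS = (
    "city",
    "tree_id",
    "compartment",
    "collection_date",
    "days_since_emergence",
    "land_use",
    "is_blank",
)


class SampleMetadata:
    """Per-sample study factors.

    Non-blank samples must carry every factor; blanks (kit negative controls)
    carry no compartment or time information.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = pd.DataFrame(df).copy()
        if validate:
            _check_unique(df.index, "sample")
            missing = [c for c in _META_COLS if c not in df.columns]
            if missing:
                raise ValidationError(f"metadata missing column(s): {missing}")
            df["is_blank"] = df["is_blank"].astype(bool)
            nb = df[~df["is_blank"]]
            bad_comp = set(nb["compartment"].dropna()) - set(COMPARTMENTS)
            if bad_comp:
                raise ValidationError(
                    f"unknown compartment label(s) {sorted(bad_comp)}; "
                    f"allowed: {list(COMPARTMENTS)}"
                )
            for col in ("city", "tree_id", "compartment", "land_use"):
                if nb[col].isna().any():
                    who = list(nb.index[nb[col].isna()])[:5]
                    raise ValidationError(f"missing {col} for non-blank sample(s) {who}")
            bad_lu = set(nb["land_use"].dropna()) - set(LAND_USES)
            if bad_lu:
                raise ValidationError(
                    f"unknown land_use label(s) {sorted(bad_lu)}; allowed {list(LAND_USES)}"
                )
        df["is_blank"] = df["is_blank"].astype(bool)
        df["days_since_emergence"] = df["days_since_emergence"].astype("Float64")
        self.df = df
        self.df.index = self.df.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def nonblank(self) -> pd.DataFrame:
        return self.df[~self.df["is_blank"]]

    def blank_ids(self) -> list[str]:
        return list(self.df.index[self.df["is_blank"]])

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all keyword equality conditions, e.g.
        ``samples_where(compartment="leaf", city="Antwerp")``."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            mask &= self.df[col] == val
        return list(self.df.index[mask])

    def subset(self, ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(ids)], validate=False)

    def write(self, path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(
        cls,
        path,
        emergence_dates: Mapping[str, _dt.date | str] | None = None,
    ) -> "SampleMetadata":
        """Read metadata TSV; (re)derive ``days_since_emergence`` from
        ``collection_date`` and the per-city emergence date."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        dates = {
            c: (pd.Timestamp(d).date() if not isinstance(d, _dt.date) else d)
            for c, d in (emergence_dates or DEFAULT_EMERGENCE_DATES).items()
        }
        df["is_blank"] = df["is_blank"].astype(bool)
        days: list[float] = []
        for sid, row in df.iterrows():
            if row["is_blank"] or pd.isna(row.get("collection_date")):
                days.append(np.nan)
                continue
            city = row["city"]
            if city not in dates:
                raise ValidationError(
                    f"no emergence date configured for city {city!r} (sample {sid!r})"
                )
            delta = pd.Timestamp(row["collection_date"]).date() - dates[city]
            days.append(float(delta.days))
        df["days_since_emergence"] = days
        return cls(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.df.equals(other.df)


def read_metadata(path, emergence_dates: Mapping[str, _dt.date | str] | None = None) -> SampleMetadata:
    """Read sample metadata, deriving days since leaf emergence per city."""
    return SampleMetadata.read(path, emergence_dates=emergence_dates)


def aggregate_to_rank(
    table: FeatureTable, taxonomy: TaxonomyTable, rank: str
) -> FeatureTable:
    """Sum features sharing a lineage down to ``rank``.

    Features unknown at ``rank`` are grouped by their nearest known higher
    rank and labelled with a rank-initial suffix (e.g. ``Beijerinckiaceae_g``).
    The grand total of reads is conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    taxonomy.check_covers(table)
    labels = taxonomy.label_at_rank(rank).loc[table.feature_ids]
    # Group on the full lineage so that identically-named genera in different
    # families do not collapse; display label is attached afterwards.
    keys = taxonomy.lineage_key(rank).loc[table.feature_ids]
    grouped = table.counts.groupby(keys.values, sort=True).sum()
    key_to_label = {}
    for key, lab in zip(keys.values, labels.values):
        key_to_label.setdefault(key, lab)
    new_index = []
    used: dict[str, int] = {}
    for key in grouped.index:
        lab = key_to_label[key]
        if lab in used:  # same display name from a different lineage
            used[lab] += 1
            lab = f"{lab}__{used[lab]}"
        else:
            used[lab] = 0
        new_index.append(lab)
    grouped.index = new_index
    return FeatureTable(grouped, validate=False)
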