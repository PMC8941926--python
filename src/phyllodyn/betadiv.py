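"""Beta-diversity machinery: Bray-Curtis, PCoA, PERMANOVA, PERMDISP2.

The permutational statistics follow the classical distance-based ANOVA
construction. With pairwise dissimilarities :math:`d_{ij}` among *n*
samples, let :math:`A = (-\\tfrac12 d_{ij}^2)` and its double-centred form
:math:`G = J A J`, :math:`J = I - \\tfrac1n \\mathbf{1}\\mathbf{1}^T`.
For a sequential (Type-I) model with terms :math:`X_1, \\dots, X_m`, the
sum of squares attributed to term *i* is

.. math:: SS_i = \\operatorname{tr}[(H_i - H_{i-1})\\, G]

where :math:`H_i` is the hat matrix of the design containing the intercept
and the first *i* terms. Residual SS is :math:`\\operatorname{tr}[(I-H_m)G]`
and the pseudo-F for term *i* uses the residual mean square. Significance
comes from free permutation of sample labels (equivalently, simultaneous
row/column permutation of *G*), with the add-one convention
:math:`p = (b+1)/(m+1)`.

PERMDISP2 (homogeneity of multivariate dispersions) embeds the samples by
principal coordinates — keeping negative-eigenvalue axes as "imaginary"
coordinates whose squared contributions subtract — measures each sample's
distance to its group centroid, and applies a one-way ANOVA F to those
distances with a label-permutation p-value.

`Permanova` and `Permdisp` are model objects: construct from a distance
matrix plus metadata, call ``.fit()``, inspect the returned results object
(``.table``/``.summary()``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .data_model import FeatureTable, SampleMetadata


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(
    table: FeatureTable | pd.DataFrame | np.ndarray,
    sample_ids: list[str] | None = None,
    relative: bool = True,
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    .. math:: d(x, y) = 1 - \\frac{2 \\sum_i \\min(x_i, y_i)}{\\sum_i x_i + \\sum_i y_i}

    Parameters
    ----------
    table
        FeatureTable (features × samples) or a plain matrix with samples in
        columns (DataFrame) / rows (ndarray).
    relative
        Convert each sample to relative abundances first (default). On
        relative abundances the metric is invariant to sample sequencing
        depth.
    """
    if isinstance(table, FeatureTable):
        if relative:
            mat = table.relative_abundance().to_numpy().T
        else:
            mat = table.counts.to_numpy().T.astype(float)
        ids = table.sample_ids
    elif isinstance(table, pd.DataFrame):
        mat = table.to_numpy().T.astype(float)
        ids = list(table.columns)
        if relative:
            mat = mat / mat.sum(axis=1, keepdims=True)
    else:
        mat = np.asarray(table, dtype=float)
        ids = sample_ids or [str(i) for i in range(mat.shape[0])]
        if relative:
            mat = mat / mat.sum(axis=1, keepdims=True)
    sums = mat.sum(axis=1)
    if np.any(sums == 0):
        bad = [ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        mins = np.minimum(mat[i], mat[i + 1:]).sum(axis=1)
        d[i, i + 1:] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1:])
    d = d + d.T
    np.clip(d, 0.0, 1.0, out=d)
    return DistanceMatrix(d, ids=ids)


@dataclass
class Ordination:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples × axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray

    def plot(self, metadata: SampleMetadata | pd.DataFrame | None = None,
             hue: str | None = None, ax=None):
        """Scatter the first two axes, optionally coloured by a metadata factor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.coordinates.iloc[:, :2]
        if metadata is not None and hue is not None:
            df = metadata.df if isinstance(metadata, SampleMetadata) else metadata
            groups = df.loc[xy.index, hue]
            for g in pd.unique(groups.dropna()):
                sub = xy[groups == g]
                ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g), s=20)
            ax.legend(title=hue, fontsize="small")
        else:
            ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1], s=20)
        ax.set_xlabel(f"PCo1 ({100 * self.proportion_explained[0]:.1f}%)")
        ax.set_ylabel(f"PCo2 ({100 * self.proportion_explained[1]:.1f}%)")
        return ax


def _gower_center(dm_values: np.ndarray) -> np.ndarray:
    a = -0.5 * dm_values.astype(float) ** 2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues — possible for semimetric dissimilarities such as
    Bray-Curtis — are reported in ``eigenvalues`` rather than silently
    dropped; coordinate axes are returned only for positive eigenvalues.
    Proportions explained are relative to the sum of positive eigenvalues.
    """
    g = _gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals[np.abs(eigvals) < 1e-10] = 0.0
    pos = eigvals > 0
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; capping"
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[pos].sum() if n_pos else 1.0
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"PCo{i+1}" for i in range(n_axes)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# design-matrix construction for sequential PERMANOVA
# ---------------------------------------------------------------------------

def _term_matrix(df: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term; ':' builds an interaction by columnwise
    products of the component encodings. Categoricals are full one-hot
    (rank handled downstream via pseudoinverse projections)."""
    parts = [p.strip() for p in term.split(":")]
    mats = []
    for p in parts:
        if p not in df.columns:
            raise KeyError(f"metadata has no column {p!r} (term {term!r})")
        col = df[p]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            mats.append(col.to_numpy(dtype=float)[:, None])
        else:
            levels = pd.unique(col.astype(str))
            if len(levels) < 2:
                raise ValueError(f"term {term!r}: factor {p!r} has a single level")
            mats.append(
                np.column_stack([(col.astype(str) == lv).to_numpy(float) for lv in levels])
            )
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(df), -1)
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class PermanovaResults:
    """Sequential PERMANOVA decomposition with permutation p-values."""

    def __init__(self, table: pd.DataFrame, n_permutations: int, seed, method: str):
        self.table = table
        self.n_permutations = n_permutations
        self.seed = seed
        self.method = method

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"].drop(index=["Residual", "Total"])

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"].drop(index=["Residual", "Total"])

    def summary(self) -> str:
        head = (
            f"PERMANOVA (sequential SS, {self.method}, "
            f"{self.n_permutations} permutations)\n"
        )
        return head + self.table.to_string(float_format=lambda v: f"{v:.4g}")

    def __repr__(self) -> str:
        return self.summary()


class Permanova:
    """Distance-based multivariate ANOVA with sequential (Type-I) terms.

    Parameters
    ----------
    dm
        Symmetric dissimilarity matrix over the samples to analyse.
    metadata
        :class:`SampleMetadata` or DataFrame indexed by sample id.
    terms
        Ordered term names; ``"a:b"`` denotes an interaction.
    """

    def __init__(
        self,
        dm: DistanceMatrix,
        metadata: SampleMetadata | pd.DataFrame,
        terms: list[str],
    ):
        df = metadata.df if isinstance(metadata, SampleMetadata) else metadata
        ids = list(dm.ids)
        missing = set(ids) - set(df.index)
        if missing:
            raise KeyError(f"samples missing metadata: {sorted(missing)[:10]}")
        self.dm = dm
        self.terms = list(terms)
        self.meta = df.loc[ids]
        base_cols = {c for t in terms for c in t.split(":")}
        sub = self.meta[[c.strip() for c in base_cols]]
        if sub.isna().any().any():
            bad = list(sub.index[sub.isna().any(axis=1)])[:5]
            raise ValueError(f"missing metadata values for samples {bad}")

        n = len(ids)
        self._g = _gower_center(dm.data)
        # cumulative hat matrices: intercept, then +term_1, +term_2, ...
        x = np.ones((n, 1))
        hats = [_hat(x)]
        dfs = []
        for t in self.terms:
            x = np.hstack([x, _term_matrix(self.meta, t)])
            h = _hat(x)
            dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
            hats.append(h)
        self._hats = hats
        self._dfs = dfs
        self._df_resid = n - int(round(np.trace(hats[-1])))
        if self._df_resid <= 0:
            raise ValueError(
                f"model uses {int(round(np.trace(hats[-1])))} df for {n} samples; "
                "no residual degrees of freedom"
            )
        # projector per term and residual projector, flattened for fast traces
        self._projs = [hats[i + 1] - hats[i] for i in range(len(self.terms))]
        self._resid_proj = np.eye(n) - hats[-1]

    def _stats(self, g: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        ss = np.array([float(np.sum(p * g)) for p in self._projs])
        ss_res = float(np.sum(self._resid_proj * g))
        ms_res = ss_res / self._df_resid
        f = (ss / np.array(self._dfs)) / ms_res
        return ss, ss_res, f

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int | None = None,
        method: str = "permutation",
    ) -> PermanovaResults:
        """Estimate the decomposition; ``method="exact"`` enumerates all
        distinct sample-label arrangements (feasible only for small n)."""
        g = self._g
        n = g.shape[0]
        ss, ss_res, f_obs = self._stats(g)
        ss_total = float(np.trace(g))
        if method == "permutation":
            rng = np.random.default_rng(seed)
            exceed = np.zeros(len(self.terms))
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                gp = g[np.ix_(perm, perm)]
                _, _, f_p = self._stats(gp)
                exceed += f_p >= f_obs - 1e-12
            pvals = (exceed + 1.0) / (n_permutations + 1.0)
            m = n_permutations
        elif method == "exact":
            count = 0
            exceed = np.zeros(len(self.terms))
            for perm in itertools.permutations(range(n)):
                gp = g[np.ix_(perm, perm)]
                _, _, f_p = self._stats(gp)
                exceed += f_p >= f_obs - 1e-12
                count += 1
            pvals = exceed / count
            m = count
        else:
            raise ValueError(f"unknown method {method!r}")

        rows = []
        for i, t in enumerate(self.terms):
            rows.append((t, self._dfs[i], ss[i], ss[i] / ss_total, f_obs[i], pvals[i]))
        rows.append(("Residual", self._df_resid, ss_res, ss_res / ss_total, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "sum_of_squares", "R2", "pseudo_F", "p_value"]
        ).set_index("term")
        return PermanovaResults(table, m, seed, method)


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: list[str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResults:
    """Convenience wrapper: ``Permanova(dm, metadata, terms).fit(...)``."""
    return Permanova(dm, metadata, terms).fit(
        n_permutations=n_permutations, seed=seed, method=method
    )


# ---------------------------------------------------------------------------
# PERMDISP2
# ---------------------------------------------------------------------------

class PermdispResults:
    def __init__(self, group_means: pd.Series, distances: pd.Series,
                 f_stat: float, p_value: float, n_permutations: int, seed):
        #: mean distance-to-centroid per group
        self.group_means = group_means
        #: per-sample distance to its group centroid
        self.distances = distances
        self.f_stat = f_stat
        self.p_value = p_value
        self.n_permutations = n_permutations
        self.seed = seed

    def summary(self) -> str:
        lines = [
            f"PERMDISP2 ({self.n_permutations} permutations)",
            f"F = {self.f_stat:.4g}, p = {self.p_value:.4g}",
            "mean distance to centroid per group:",
            self.group_means.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return self.summary()


def _dispersion_distances(dm: DistanceMatrix, groups: pd.Series) -> pd.Series:
    """Distance of each sample to its group centroid in the full PCoA space,
    with negative-eigenvalue axes contributing negatively (imaginary-part
    correction; squared distances are clipped at zero)."""
    g = _gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals[np.abs(eigvals) < 1e-10] = 0.0
    pos = eigvals > 0
    neg = eigvals < 0
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    ids = list(dm.ids)
    out = pd.Series(0.0, index=ids)
    for gname in pd.unique(groups):
        idx = np.flatnonzero((groups == gname).to_numpy())
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        out.iloc[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for k in range(n_groups):
        v = values[codes == k]
        ss_b += v.size * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_w == 0.0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


class Permdisp:
    """Homogeneity of multivariate dispersions (PERMDISP2)."""

    def __init__(self, dm: DistanceMatrix, metadata: SampleMetadata | pd.DataFrame,
                 grouping: str):
        df = metadata.df if isinstance(metadata, SampleMetadata) else metadata
        groups = df.loc[list(dm.ids), grouping].astype(str)
        sizes = groups.value_counts()
        if len(sizes) < 2:
            raise ValueError("need at least two groups")
        if (sizes < 2).any():
            raise ValueError(
                f"singleton group(s): {list(sizes.index[sizes < 2])}"
            )
        self.dm = dm
        self.groups = groups

    def fit(self, n_permutations: int = 999, seed: int | None = None) -> PermdispResults:
        dist = _dispersion_distances(self.dm, self.groups)
        codes, uniques = pd.factorize(self.groups)
        k = len(uniques)
        vals = dist.to_numpy()
        f_obs = _anova_f(vals, codes, k)
        # Freedman-Lane style scheme: permute the residuals of the
        # distances-on-groups fit, then recompute the ANOVA F on the original
        # grouping (the scheme of the reference PERMDISP2 implementation;
        # permuting raw distances is mildly anticonservative because
        # distances within a group share an estimated centroid).
        group_means = np.array([vals[codes == g].mean() for g in range(k)])
        resid = vals - group_means[codes]
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_permutations):
            f_p = _anova_f(resid[rng.permutation(vals.size)], codes, k)
            if f_p >= f_obs - 1e-12:
                b += 1
        p = (b + 1) / (n_permutations + 1)
        means = dist.groupby(self.groups).mean()
        return PermdispResults(means, dist, f_obs, p, n_permutations, seed)


def permdisp(
    dm: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    grouping: str,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermdispResults:
    """Convenience wrapper: ``Permdisp(dm, metadata, grouping).fit(...)``."""
    return Permdisp(dm, metadata, grouping).fit(n_permutations=n_permutations, seed=seed)
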