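"""Synthetic phyllosphere chronosequence generator with ground truth.

The generator emulates the statistical structure of a two-city urban-tree
phyllosphere study: four compartments (leaf, bud, branch, trunk) sampled on
several trees over a spring chronosequence, with

* four planted temporal ASV clusters on the leaves — **general** (constant,
  abundant everywhere), **early** (exponentially decaying after leaf
  emergence), **middle** (Gaussian bump mid-window) and **late**
  (saturating rise, amplified on street trees by a land-use factor),
* strong compartment effects and moderate tree/city effects on composition,
* compartment-dependent sequencing depth with a heavy chloroplast load on
  leaves and buds (so leaf samples become depth-poor once chloroplast reads
  are filtered),
* kit blanks carrying external contaminants (kit/human-associated genera)
  plus small cross-contamination leakage from the most abundant sample
  taxa, and
* a handful of archaeal and chloroplast features exercising the
  non-bacterial filter.

Per-sample expected compositions are softmax-combined log-weights; realised
compositions add Dirichlet overdispersion and counts are multinomial at a
lognormal depth. Everything is driven by one integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_EMERGENCE_DATES,
    RANKS,
    UNKNOWN,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
)

_PHYLLO_GENERA = {
    "general": ["Sphingomonas", "Hymenobacter", "Mucilaginibacter",
                "Methylobacterium", "Pseudomonas"],
    "early": ["Hymenobacter", "Sphingomonas", "Edaphobacter", "Chthoniobacter"],
    "middle": ["Chamaesiphon", "Paracoccus", "Thermomonas", "Qipengyuania",
               "Pseudarthrobacter"],
    "late": ["Massilia", "Bacillus", "Erwinia", "Pantoea", "Skermanella",
             "Clostridium", "Noviherbaspirillum"],
}
_KIT_GENERA = ["Ralstonia", "Cupriavidus", "Delftia", "Cutibacterium",
               "Corynebacterium", "Staphylococcus", "Streptococcus",
               "Escherichia", "Enterococcus", "Lactobacillus"]


@dataclass
class CityConfig:
    name: str
    n_trees: int
    days: tuple[float, ...]  # sampling days relative to leaf emergence
    n_street: int = 2  # first n_street trees are street trees, rest park


@dataclass
class GeneratorConfig:
    """All knobs of the generator; presets fill in study-like values."""

    cities: tuple[CityConfig, ...]
    compartments: tuple[str, ...] = ("leaf", "bud", "branch", "trunk")
    # planted cluster sizes (leaf ASVs)
    n_general: int = 40
    n_early: int = 30
    n_middle: int = 30
    n_late: int = 30
    n_background: int = 600
    # effect sizes (log-abundance scale)
    compartment_affinity: float = 2.0  # background home-compartment boost
    background_leaf_penalty: float = 4.0  # background on leaves: rare tail only
    cluster_other_compartment: float = 0.5
    general_kernel: float = 2.2
    early_amplitude: float = 5.0
    early_decay_days: float = 5.0
    middle_amplitude: float = 2.6
    middle_peak_day: float = 14.0
    middle_width_days: float = 5.0
    late_amplitude: float = 3.6
    late_midpoint_day: float = 24.0
    late_rise_days: float = 4.0
    landuse_late_multiplier: float = 1.0  # extra street gain on the late kernel
    # urban late arrivals are dispersal-limited: park trees barely receive
    # them (log-weight penalty applied off-street)
    late_park_penalty: float = 6.0
    tree_sd: float = 0.2
    # per-cluster tree-effect scales: the general cluster is ubiquitous
    # across trees, while early colonisation and urban late arrivals are
    # dispersal-limited and tree-specific
    tree_sd_by_cluster: dict = field(default_factory=lambda: {
        "general": 0.2, "early": 0.2, "middle": 0.2, "late": 0.2})
    city_sd: float = 0.4
    base_sd: float = 1.0
    # successional-cluster members span a narrower abundance range than the
    # full community (they are the established, moderately abundant taxa)
    cluster_base_sd: float = 0.5
    dirichlet_concentration: float = 3000.0
    # depths (lognormal median per compartment) and chloroplast load
    depth_median: dict = field(default_factory=lambda: {
        "leaf": 3000.0, "bud": 2800.0, "branch": 24000.0, "trunk": 31000.0})
    depth_sigma: dict = field(default_factory=lambda: {
        "leaf": 1.0, "bud": 1.0, "branch": 0.6, "trunk": 0.6})
    chloroplast_fraction: dict = field(default_factory=lambda: {
        "leaf": 0.8, "bud": 0.78, "branch": 0.05, "trunk": 0.02})
    # contamination
    n_external: int = 10
    n_cross: int = 5
    n_blanks_per_city: int = 3
    blank_external_mean: float = 60.0
    blank_cross_mean: float = 5.0
    sample_external_mean: float = 4.0
    sample_external_presence: float = 0.5
    # non-bacterial extras
    n_chloroplast_features: int = 3
    n_archaea: int = 2
    include_blanks: bool = True
    include_chloroplast: bool = True
    # which days each compartment is sampled on (leaves exist only after
    # emergence, buds only around it)
    leaf_min_day: float = 2.0
    bud_max_day: float = 7.0

    def validate(self) -> None:
        if self.n_general + self.n_early + self.n_middle + self.n_late == 0 \
                and self.n_background == 0:
            raise ValueError("config plants no features at all")
        if not self.cities:
            raise ValueError("need at least one city")
        for c in self.cities:
            if c.n_trees < 1 or len(c.days) < 1:
                raise ValueError(f"infeasible city config {c}")


@dataclass
class SyntheticTruth:
    """Ground truth written next to every generated data set."""

    cluster_labels: pd.Series  # feature -> general/early/middle/late/background/...
    contaminant_role: pd.Series  # feature -> external/cross/none
    true_composition: pd.DataFrame  # bacterial features × non-blank samples
    chloroplast_fraction: pd.Series  # per non-blank sample
    depths: pd.Series  # drawn bacterial depth per non-blank sample
    seed: int | None
    config: GeneratorConfig

    @property
    def external_ids(self) -> list[str]:
        return list(self.contaminant_role.index[self.contaminant_role == "external"])

    @property
    def cross_ids(self) -> list[str]:
        return list(self.contaminant_role.index[self.contaminant_role == "cross"])

    def planted_cluster(self, feature_ids) -> pd.Series:
        return self.cluster_labels.loc[list(feature_ids)]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "cluster_labels": self.cluster_labels.to_dict(),
            "contaminant_role": self.contaminant_role.to_dict(),
            "chloroplast_fraction": self.chloroplast_fraction.to_dict(),
            "depths": self.depths.to_dict(),
            "config": _config_to_jsonable(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _config_to_jsonable(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["cities"] = [asdict(c) for c in cfg.cities]
    return d


def preset(name: str) -> GeneratorConfig:
    """Named generator configurations.

    * ``paper_like`` — 2 cities × 4 trees × 4 compartments, 10/5 time
      points, ≈1500 ASVs: the study-scale conditions.
    * ``tiny`` — desk-test scale (≤ 200 ASVs, ≤ 40 samples).
    * ``null_model`` — one compartment, no compartment/time/cluster/tree
      effects; for type-I-error calibration of the permutation tests.
    """
    if name == "paper_like":
        return GeneratorConfig(
            cities=(
                CityConfig("Antwerp", 4, (-7, -3, 2, 4, 7, 14, 21, 28, 35, 42)),
                CityConfig("Milan", 4, (0, 7, 14, 28, 42)),
            ),
            n_background=1350,
        )
    if name == "tiny":
        return GeneratorConfig(
            cities=(CityConfig("Antwerp", 2, (3, 7, 14, 21, 28), n_street=1),),
            n_general=10, n_early=8, n_middle=8, n_late=8, n_background=80,
            n_external=6, n_cross=3, n_blanks_per_city=2,
            depth_median={"leaf": 1500.0, "bud": 1400.0,
                          "branch": 6000.0, "trunk": 8000.0},
            leaf_min_day=0.0,
        )
    if name == "null_model":
        return GeneratorConfig(
            cities=(CityConfig("Antwerp", 4, tuple(float(d) for d in range(0, 98, 7)),
                               n_street=2),),
            compartments=("leaf",),
            n_general=0, n_early=0, n_middle=0, n_late=0, n_background=100,
            compartment_affinity=0.0, tree_sd=0.0, city_sd=0.0,
            landuse_late_multiplier=1.0,
            n_external=0, n_cross=0, n_blanks_per_city=0,
            n_chloroplast_features=0, n_archaea=0,
            include_blanks=False, include_chloroplast=False,
            depth_median={"leaf": 2000.0}, depth_sigma={"leaf": 0.0},
            chloroplast_fraction={"leaf": 0.0},
            leaf_min_day=-np.inf,
        )
    raise ValueError(f"unknown preset {name!r}; choose paper_like, tiny or null_model")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_taxonomy(rng: np.random.Generator, labels: pd.Series) -> TaxonomyTable:
    rows = {}
    fam_pool = [f"Family{i:03d}" for i in range(60)]
    unknown_fams = ["EU289441", "EU861940", "ALVU"]
    for fid, lab in labels.items():
        if lab == "chloroplast":
            rows[fid] = ("Bacteria", "Cyanobacteria", "Chloroplast",
                         UNKNOWN, UNKNOWN, UNKNOWN)
        elif lab == "archaea":
            rows[fid] = ("Archaea", "Euryarchaeota", UNKNOWN, UNKNOWN,
                         UNKNOWN, UNKNOWN)
        elif lab in _PHYLLO_GENERA:
            genus = rng.choice(_PHYLLO_GENERA[lab])
            if rng.random() < 0.15:  # some ASVs unknown at genus level
                fam = rng.choice(unknown_fams)
                rows[fid] = ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                             "OrderA", fam, UNKNOWN)
            else:
                rows[fid] = ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                             "OrderA", f"{genus}aceae", genus)
        elif lab == "external":
            genus = _KIT_GENERA[int(fid.split("_")[-1]) % len(_KIT_GENERA)]
            rows[fid] = ("Bacteria", "Firmicutes", "Bacilli", "OrderK",
                         f"{genus}aceae", genus)
        else:  # background
            fam = fam_pool[rng.integers(len(fam_pool))]
            rows[fid] = ("Bacteria", "PhylumB", "ClassB", "OrderB", fam,
                         f"Genus{rng.integers(400):03d}")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(df, validate=False)


def generate(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[FeatureTable, SampleMetadata, TaxonomyTable, SyntheticTruth]:
    """Draw one synthetic data set with its ground truth."""
    config.validate()
    rng = np.random.default_rng(seed)

    # ---- feature roster ---------------------------------------------------
    labels: dict[str, str] = {}
    for lab, n in (("general", config.n_general), ("early", config.n_early),
                   ("middle", config.n_middle), ("late", config.n_late),
                   ("background", config.n_background)):
        for i in range(n):
            labels[f"ASV_{lab}_{i:04d}"] = lab
    externals = [f"ASV_external_{i:04d}" for i in range(config.n_external)]
    for fid in externals:
        labels[fid] = "external"
    archaea = [f"ASV_archaea_{i:02d}" for i in range(config.n_archaea)]
    for fid in archaea:
        labels[fid] = "archaea"
    chloro = [f"ASV_chloroplast_{i:02d}" for i in range(config.n_chloroplast_features)] \
        if config.include_chloroplast else []
    for fid in chloro:
        labels[fid] = "chloroplast"
    label_ser = pd.Series(labels)
    features = list(label_ser.index)
    n_feat = len(features)
    lab_arr = label_ser.to_numpy()

    # ---- per-feature random effects ---------------------------------------
    base = rng.normal(0.0, config.base_sd, n_feat)
    is_cluster_f = np.isin(label_ser.to_numpy(),
                           ["general", "early", "middle", "late"])
    base[is_cluster_f] = rng.normal(0.0, config.cluster_base_sd,
                                    int(is_cluster_f.sum()))
    comps = list(config.compartments)
    # Background features get one home compartment. Leaves are excluded as a
    # home when other compartments exist: the abundant leaf community is the
    # successional assemblage itself (the planted clusters); background taxa
    # reach leaves only as the rare tail.
    nonleaf = [i for i, c in enumerate(comps) if c != "leaf"] or [0]
    home = np.asarray(nonleaf)[rng.integers(len(nonleaf), size=n_feat)]
    city_names = [c.name for c in config.cities]
    city_off = {c: rng.normal(0.0, config.city_sd, n_feat) for c in city_names}
    sd_vec = np.full(n_feat, config.tree_sd)
    for lab, sd in config.tree_sd_by_cluster.items():
        sd_vec[label_ser.to_numpy() == lab] = sd
    tree_off = {}
    for c in config.cities:
        for t in range(c.n_trees):
            tree_off[f"{c.name}_T{t+1}"] = rng.normal(0.0, 1.0, n_feat) * sd_vec

    is_cluster = np.isin(lab_arr, ["general", "early", "middle", "late"])
    is_bg = lab_arr == "background"
    is_ext = lab_arr == "external"
    is_arch = lab_arr == "archaea"
    bacterial = ~np.isin(lab_arr, ["chloroplast"])

    def kernel(lab: str, t: float, street: bool) -> float:
        if lab == "general":
            return config.general_kernel
        if lab == "early":
            return config.early_amplitude * np.exp(-max(t, 0.0) / config.early_decay_days)
        if lab == "middle":
            return config.middle_amplitude * np.exp(
                -((t - config.middle_peak_day) ** 2) / (2 * config.middle_width_days ** 2)
            )
        if lab == "late":
            k = config.late_amplitude / (
                1.0 + np.exp(-(t - config.late_midpoint_day) / config.late_rise_days)
            )
            if street:
                return k * config.landuse_late_multiplier
            return k - config.late_park_penalty
        return 0.0

    # cluster presence in other compartments: general everywhere, early in
    # all woody compartments at low level, middle in buds, late leaf-only
    other_comp_allowed = {
        "general": set(comps),
        "early": set(comps),
        "middle": {"leaf", "bud"} & set(comps),
        "late": {"leaf"},
    }

    # ---- samples -----------------------------------------------------------
    sample_rows = []
    comp_list = []
    for city in config.cities:
        emergence = DEFAULT_EMERGENCE_DATES.get(city.name, _dt.date(2018, 4, 15))
        for t in range(city.n_trees):
            tree = f"{city.name}_T{t+1}"
            street = t < city.n_street
            for day in city.days:
                for comp in comps:
                    if comp == "leaf" and day < config.leaf_min_day:
                        continue
                    if comp == "bud" and day > config.bud_max_day:
                        continue
                    sid = f"{city.name[:3]}_{tree.split('_')[-1]}_{comp}_d{int(day):+04d}"
                    sample_rows.append(
                        dict(sample_id=sid, city=city.name, tree_id=tree,
                             compartment=comp,
                             collection_date=str(emergence + _dt.timedelta(days=int(day))),
                             days_since_emergence=float(day),
                             land_use="street" if street else "park",
                             is_blank=False)
                    )
                    comp_list.append((sid, city.name, tree, comp, float(day), street))

    sample_ids = [r["sample_id"] for r in sample_rows]
    n_samp = len(sample_ids)

    # ---- expected compositions (bacterial, contaminant-free) ---------------
    model_mask = (is_cluster | is_bg) & bacterial
    model_idx = np.flatnonzero(model_mask)
    logw = np.full((n_feat, n_samp), -np.inf)
    comp_index = {c: i for i, c in enumerate(comps)}
    for j, (sid, cityname, tree, comp, day, street) in enumerate(comp_list):
        w = np.full(n_feat, -np.inf)
        # background: home-compartment affinity; on leaves only a rare tail
        bg = is_bg
        if comp == "leaf" and len(comps) > 1:
            bg_level = base[bg] - config.background_leaf_penalty
        else:
            bg_level = base[bg] + np.where(
                home[bg] == comp_index[comp],
                config.compartment_affinity,
                -config.compartment_affinity,
            )
        w[bg] = bg_level + city_off[cityname][bg] + tree_off[tree][bg]
        # clusters
        for lab in ("general", "early", "middle", "late"):
            m = lab_arr == lab
            if not m.any():
                continue
            if comp == "leaf":
                w[m] = (base[m] + kernel(lab, day, street)
                        + city_off[cityname][m] + tree_off[tree][m])
            elif comp in other_comp_allowed[lab]:
                w[m] = (base[m] + config.cluster_other_compartment
                        + city_off[cityname][m] + tree_off[tree][m])
        # archaea: rare, woody compartments only
        if comp in ("branch", "trunk"):
            w[is_arch] = base[is_arch] - 4.0
        logw[:, j] = w

    finite = np.isfinite(logw)
    expw = np.where(finite, np.exp(logw - np.nanmax(np.where(finite, logw, np.nan),
                                                    axis=0, keepdims=True)), 0.0)
    p_true = expw / expw.sum(axis=0, keepdims=True)

    # ---- draw counts -------------------------------------------------------
    counts = np.zeros((n_feat, n_samp), dtype=np.int64)
    depths = np.zeros(n_samp)
    chl_frac = np.zeros(n_samp)
    conc = config.dirichlet_concentration
    chloro_split = None
    if chloro:
        chloro_split = rng.dirichlet(np.full(len(chloro), 2.0))
    chloro_rows = [features.index(f) for f in chloro]
    ext_rows = [features.index(f) for f in externals]
    for j, (sid, cityname, tree, comp, day, street) in enumerate(comp_list):
        med = config.depth_median[comp]
        sig = config.depth_sigma[comp]
        depth = max(int(np.round(np.exp(rng.normal(np.log(med), sig)))), 50)
        depths[j] = depth
        p = p_true[:, j]
        alpha = conc * p
        pos = alpha > 0
        gam = np.zeros(n_feat)
        gam[pos] = rng.gamma(alpha[pos])
        q = gam / gam.sum() if gam.sum() > 0 else p
        counts[:, j] = rng.multinomial(depth, q)
        # external contaminants leak into real samples at trace level
        for r in ext_rows:
            if rng.random() < config.sample_external_presence:
                counts[r, j] += rng.poisson(config.sample_external_mean) + 1
        # chloroplast load on top of the bacterial reads
        f = config.chloroplast_fraction.get(comp, 0.0)
        if chloro and f > 0:
            n_chl = int(np.round(depth * f / (1.0 - f)))
            chl = rng.multinomial(n_chl, chloro_split)
            for r, c in zip(chloro_rows, chl):
                counts[r, j] += c
            chl_frac[j] = n_chl / (n_chl + depth)

    # ---- cross-contaminants: most abundant sample taxa --------------------
    mean_rel = (counts[model_idx] / np.maximum(counts.sum(axis=0), 1)).mean(axis=1)
    order = np.argsort(mean_rel)[::-1]
    cross_rows = [int(model_idx[i]) for i in order[: config.n_cross]]
    cross_ids = [features[r] for r in cross_rows]
    role = pd.Series("none", index=features)
    role[externals] = "external"
    role[cross_ids] = "cross"

    # ---- blanks ------------------------------------------------------------
    if config.include_blanks and config.n_blanks_per_city > 0:
        for city in config.cities:
            for b in range(config.n_blanks_per_city):
                sid = f"{city.name[:3]}_blank_{b+1}"
                col = np.zeros(n_feat, dtype=np.int64)
                for r in ext_rows:
                    col[r] = rng.poisson(config.blank_external_mean) + 1
                for r in cross_rows:
                    col[r] = rng.poisson(config.blank_cross_mean) + 1
                counts = np.column_stack([counts, col])
                sample_rows.append(
                    dict(sample_id=sid, city=city.name, tree_id=np.nan,
                         compartment=np.nan, collection_date=np.nan,
                         days_since_emergence=np.nan, land_use=np.nan,
                         is_blank=True)
                )
                sample_ids.append(sid)

    table = FeatureTable(
        pd.DataFrame(counts, index=features, columns=sample_ids), validate=False
    )
    meta_df = pd.DataFrame(sample_rows).set_index("sample_id")
    metadata = SampleMetadata(meta_df, validate=False)
    taxonomy = _make_taxonomy(rng, label_ser)
    truth = SyntheticTruth(
        cluster_labels=label_ser,
        contaminant_role=role,
        # composition over the analysed (bacterial, non-contaminant) features,
        # renormalised after dropping the archaeal/chloroplast mass
        true_composition=pd.DataFrame(
            p_true[model_idx][:, : len(comp_list)]
            / p_true[model_idx][:, : len(comp_list)].sum(axis=0, keepdims=True),
            index=[features[i] for i in model_idx],
            columns=[r[0] for r in comp_list],
        ),
        chloroplast_fraction=pd.Series(chl_frac, index=[r[0] for r in comp_list]),
        depths=pd.Series(depths, index=[r[0] for r in comp_list]),
        seed=seed,
        config=config,
    )
    return table, metadata, taxonomy, truth
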