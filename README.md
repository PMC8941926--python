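# phyllodyn

Succession analysis of bacterial phyllosphere communities on emerging tree
leaves.

When deciduous trees leaf out in spring, a fresh habitat appears and is
colonised in waves: pioneer taxa arrive first, transient guilds rise and
fall, and late arrivals — often from urban sources around street trees —
establish weeks later, all against a backdrop of generalists shared with
buds, branches and trunk. `phyllodyn` is a toolkit for analysing such
chronosequences from 16S amplicon ASV tables. It is aimed at microbial
ecologists who have a denoised count table, a taxonomy and per-sample
metadata (city, tree, compartment, sampling day, land use, blanks) and
want the full downstream analysis to be scripted, seeded and testable.

The pipeline covers:

* validated containers and I/O for counts / taxonomy / metadata, with
  genus-level aggregation (`data_model`);
* post-denoising filters — non-bacterial (chloroplast, Archaea) removal,
  read-length windows, a 200-read sample-depth cut (`preprocess`);
* rule-based blank decontamination separating **external** contaminants
  (kit/human-associated; removed) from **cross** contaminants (abundant
  sample taxa leaked into blanks; kept), plus a read-count presence
  threshold derived from the contaminant distribution (`decontam`);
* beta diversity: Bray-Curtis, PCoA, sequential-SS PERMANOVA and
  PERMDISP2, all implemented in-package with permutation inference
  (`betadiv`);
* community dynamics: change rate between consecutive time points and
  between-tree heterogeneity within time points, with Kendall tau-b trend
  tests (`dynamics`);
* the core procedure: **rarefaction-bootstrapped co-occurrence
  clustering** of leaf ASVs into successional groups with per-ASV support
  (`succession`);
* core genera and IndVal indicator taxa per compartment
  (`compartment_taxa`), and presence-based cluster-compartment overlap,
  tree ubiquity and shared-taxon fractions (`overlap`);
* a fully seeded synthetic-data generator with ground truth for every
  stage (`synth`).

## The core statistics

Bray-Curtis dissimilarity between samples *x*, *y*:
d(x,y) = 1 − 2·Σᵢ min(xᵢ,yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ).

PERMANOVA partitions the Gower-centred squared-distance matrix over an
ordered term list (sequential sums of squares, hat-matrix traces);
R² = SS_term/SS_total and p-values come from free label permutation,
p = (b+1)/(m+1). PERMDISP2 tests homogeneity of dispersions via distances
to group centroids in full PCoA space.

The succession procedure repeats, for each of *n* random rarefactions to a
fixed depth (default 912 reads/sample): drop ASVs under 25 total reads,
scale each ASV row to unit mass, Euclidean distances between profiles,
Ward (minimum-variance) clustering, cut at *k* (chosen once by mean
silhouette width on a deterministic reference table). Replicate clusters
are matched to the reference by optimal one-to-one overlap assignment, and
an ASV's **support** for a cluster is the fraction of replicates in which
it landed there; each ASV is assigned to its argmax cluster and the
clusters are named general / early / middle / late from their temporal
profiles. IndVal indicator values are √(A·B) with A the group-size
corrected specificity and B the occurrence fidelity.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```python
from phyllodyn import synth, decontam, betadiv, dynamics
from phyllodyn.preprocess import preprocess
from phyllodyn.data_model import aggregate_to_rank
from phyllodyn.succession import SuccessionClustering, name_clusters

# a study-scale synthetic data set (2 cities x 4 trees x 4 compartments)
table, metadata, taxonomy, truth = synth.generate(
    synth.preset("paper_like"), seed=42)

clean, reports = preprocess(table, taxonomy)          # filters
calls = decontam.classify_blank_features(clean, metadata, taxonomy)
clean, report = decontam.remove_external(clean, calls, metadata)

genus = aggregate_to_rank(clean, taxonomy, "genus")
dm = betadiv.bray_curtis(genus)
print(betadiv.permanova(dm, metadata,
                        ["compartment", "city", "land_use"],
                        n_permutations=999, seed=0).summary())

leaf_ids = [s for s in metadata.samples_where(compartment="leaf",
                                              city="Antwerp")
            if s in set(clean.sample_ids)]
leaf = clean.select_samples(leaf_ids).drop_empty_features()
fit = SuccessionClustering(leaf, n_replicates=200, depth=912,
                           min_total=25).fit(seed=1)
print(fit.summary())
print(name_clusters(leaf, fit, metadata))

trend = dynamics.kendall_trend(
    dynamics.consecutive_dissimilarity(leaf, metadata, "leaf"))
print(f"leaf change-rate trend: tau = {trend.tau:.2f}, "
      f"p = {trend.p_value:.2g}, n = {trend.n}")
```

Output:

```
PERMANOVA (sequential SS, permutation, 999 permutations)
              df  sum_of_squares       R2  pseudo_F  p_value
term
compartment    3           56.19   0.8331     346.2    0.001
city           1           0.661 0.009799     12.22    0.001
land_use       1          0.3177  0.00471     5.872    0.001
Residual     190           10.28   0.1524       NaN      NaN
Total        195           67.45        1       NaN      NaN
Rarefaction-bootstrap co-occurrence clustering (200 replicates, k = 4)
130 ASVs assigned; k-mismatch replicates: 0
cluster sizes: C1: 30, C2: 30, C3: 40, C4: 30
median assignment support: 1.000
silhouette profile: k=2: 0.513, k=3: 0.528, k=4: 0.574, k=5: 0.498, ...
{'C3': 'general', 'C2': 'early', 'C4': 'middle', 'C1': 'late'}
leaf change-rate trend: tau = -0.30, p = 0.031, n = 28
```

Reading the numbers: phyllosphere compartment explains 83% of the
Bray-Curtis variation in this synthetic data set (all three factors
significant at the permutation floor of 0.001); silhouette selection picks
k = 4 clusters whose sizes match the four planted successional groups, and
every ASV's membership is stable across the 200 rarefactions (median
support 1.0); the negative Kendall trend (τ = −0.30) says the leaf
communities change fastest right after emergence and stabilise over the
six-week window.

The same pipeline is scriptable from the shell (`phyllodyn synth`,
`phyllodyn preprocess`, `phyllodyn decontam`, `phyllodyn betadiv`,
`phyllodyn dynamics`, `phyllodyn succession`, `phyllodyn indicators`,
`phyllodyn overlap`); real data enter as plain TSV tables.

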