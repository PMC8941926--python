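# Methods

`phyllodyn` analyses bacterial community succession on emerging tree leaves
from 16S amplicon count tables. This note documents the statistical
procedures, the choices made where a procedure is under-determined, the
synthetic-data generator used for validation, and the limits of what the
validation shows.

## Data model and filtering

Counts live in a feature × sample integer matrix (`FeatureTable`);
taxonomy is a six-rank lineage (domain … genus) with an explicit
unknown-rank marker; sample metadata carries city, tree individual,
phyllosphere compartment (leaf / bud / branch / trunk), collection date,
days since leaf emergence (derived from a per-city emergence date,
defaults 11 April for Milan and 17 April for Antwerp), land use
(park / street) and a blank flag.

Aggregation to a rank sums features sharing a lineage; features unknown at
the target rank are grouped under their nearest known ancestor with a
rank-initial suffix (an unknown genus in family `EU289441` becomes
`EU289441_g`), so labels remain unique and display like standard amplicon
reports. Aggregation conserves the grand read total exactly.

Pre-analysis filters, in order: (1) remove non-bacterial features
(chloroplast, mitochondria, Archaea, unassigned domain; configurable
patterns); (2) remove features whose representative-sequence length falls
outside a per-batch window (V4 libraries differ between runs; defaults
251–256 bp and 234–265 bp are typical); (3) remove samples with fewer than
200 reads. All boundaries are strict in the "less than / more than" sense:
the boundary value itself survives. The depth cut runs last because
chloroplast removal is what makes leaf and bud samples depth-poor; running
it first would keep samples that are empty after step 1.

## Blank-based decontamination

Features observed in kit blanks are classified by explicit rules replacing
the manual taxon-by-taxon curation such data normally receive:

1. user whitelist → cross-contaminant (kept); user blacklist → external
   (removed);
2. dominance: mean relative abundance across real samples in the top
   decile → cross (an abundant genuine taxon that leaked into the blanks);
3. genus on a kit/human-contaminant list (Ralstonia, Cupriavidus, Delftia,
   Cutibacterium, Corynebacterium, staphylococci/streptococci, enteric
   genera, …) → external;
4. anything else → external (conservative), flagged for review.

External features are removed entirely, then blanks are dropped. The
distribution of contaminant counts in real samples defines the **presence
threshold**: the smallest integer *t* such that requiring
`count > t` for presence discards at least a target fraction (default
one half) of contaminant presence instances, where an instance is one
(contaminant, sample) pair with a nonzero count. With the default data
conditions this lands near the conventional "> 10 reads" presence rule
used downstream. The threshold is monotone in the target fraction by
construction.

## Beta diversity

Bray-Curtis dissimilarity, computed on relative abundances by default
(flag to use raw counts):

d(x, y) = 1 − 2·Σᵢ min(xᵢ, yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ).

**PCoA** is classical scaling: double-centre −½d², eigendecompose, order
axes by decreasing eigenvalue. Negative eigenvalues (possible for
semimetric dissimilarities) are reported, never silently dropped;
proportions explained are taken over the positive part.

**PERMANOVA** partitions the Gower-centred matrix G = J(−½D²)J over an
ordered term list with sequential (Type-I) sums of squares via cumulative
hat matrices: SSᵢ = tr[(Hᵢ − Hᵢ₋₁)G]; pseudo-F uses the residual mean
square; R² = SSᵢ/SS_total. Categorical terms are one-hot encoded (rank
handled through pseudoinverse projections), numeric terms enter linearly,
interactions are columnwise products. Significance is by free permutation
of sample labels (no strata) with the add-one convention
p = (b+1)/(m+1); an `exact` mode enumerates all label orderings for small
n. Term order matters under sequential SS and defaults to the
main-effects-then-interactions order of the study design.

**PERMDISP2** embeds samples in the full PCoA space — negative-eigenvalue
axes kept as imaginary coordinates whose squared contributions subtract,
clipped at zero — measures each sample's distance to its group centroid,
and applies a one-way ANOVA F. The permutation scheme permutes the
*residuals* of the distances-on-groups fit and recomputes F on the original
grouping (the scheme of the reference R implementation, reproduced here
and cross-checked against it on identical distance matrices; permuting raw
distances is measurably anticonservative because distances within a group
share an estimated centroid).

## Community dynamics

For one compartment, the **consecutive** series holds the Bray-Curtis
dissimilarity between each tree's samples at adjacent retained time
points, timestamped at the later day (the change is realised by then); the
**within-time-point** series holds all between-tree dissimilarities at
each day. Trends over days since emergence use Kendall's tau-b
(tie-corrected; exact p for small untied samples, tie-corrected normal
approximation otherwise).

Adjacent records of the consecutive series share their middle sample and
are therefore positively dependent; trend tests on the full series are
mildly anticonservative under the null (measured ≈ 0.08–0.11 at α = 0.05
in simulation). `consecutive_dissimilarity(..., disjoint=True)` keeps
every other interval so that no two records share a sample; this
exchangeable variant is what the type-I calibration uses (measured rate
0.050 over 3,000 null data sets). The full overlapping series remains the
default descriptive statistic, as is conventional.

## Succession clustering (rarefaction-bootstrapped co-occurrence)

The core procedure, applied to one compartment's table (typically Antwerp
leaves):

1. rarefy each sample without replacement (multivariate hypergeometric) to
   a fixed depth (default 912 reads; shallower samples are dropped);
2. drop ASVs with total rarefied abundance below 25 reads;
3. scale each ASV's row by its total, giving unit-mass profiles;
4. Euclidean distances between profiles → Ward minimum-variance
   agglomeration (Ward.D2 convention; ties resolved by the deterministic
   nearest-neighbour-chain order) → cut into k clusters;
5. repeat for n independent rarefactions (default 1,000; one RNG substream
   per replicate spawned from the master seed, so results are independent
   of execution order); per replicate, clusters are matched to a reference
   clustering by optimal one-to-one assignment on shared-feature counts
   (rectangular Hungarian; surplus clusters fall back to greedy best
   overlap and are counted in a mismatch diagnostic);
6. the **support** of an ASV for a cluster is the fraction of the n
   replicates in which it landed in that (matched) cluster; every ASV that
   survived filtering at least once is assigned to its argmax cluster
   (ties break to the lowest cluster index). Support rows of ASVs retained
   in all replicates sum to exactly 1; others sum to less.

The **reference clustering** is computed on the *expected* rarefied table:
each retained sample's counts scaled deterministically to depth·c/N, the
abundance threshold applied to the expected totals, then steps 3–4. This
keeps the 25-read threshold on the same scale as the replicates while
involving no randomness; thresholding the raw unrarefied table instead
retains a large rare tail that no replicate ever sees, which distorts
silhouette-based k selection.

k policy: one silhouette decision on the reference table (mean silhouette
width over the cut, Euclidean distances, singleton clusters scored 0, ties
to the smallest k, candidate range 2–8), then that k is fixed for all
replicates; per-replicate re-selection is available behind a flag.

Clusters are named post hoc from their time series: the cluster with the
highest overall mean relative abundance is **general**; the rest are
ranked by abundance-weighted mean day and named **early / middle / late**.
Per-sample cluster abundances (plus an "other" pool for never-retained
features) sum to 1.

## Compartment-associated taxa

A genus is **core** to a compartment when present (count strictly > 10
reads, the decontamination-derived threshold) in strictly more than 95% of
that compartment's samples. Raising either threshold can only shrink the
core set.

**Indicator analysis** scores genera against compartments and pairs of
compartments with the group-size-corrected indicator value
IndVal.g = √(A·B): A (specificity) is the genus's summed per-group mean
abundance within the target combination over the sum across all groups —
per-group means, not pooled sample means, so unequal group sizes do not
bias A — and B (fidelity) is the occurrence fraction within the
combination. p-values come from permuting group labels; Benjamini-Hochberg
controls the FDR across genus × combination tests. Only each city's final
time point enters by default, avoiding temporal pseudo-replication of the
same trees. Because CLR-transformed abundances (log count-plus-pseudocount
minus the sample's mean log; pseudocount default 1) are negative-valued
and IndVal needs non-negative input, the CLR mode shifts each genus by its
global minimum before scoring; a plain relative-abundance mode is the
alternative, and the choice is explicit in the API.

## Overlap and ubiquity

Presence uses `count > 10` in at least one sample of the group. Per leaf
cluster, member ASVs are decomposed into mutually exclusive categories —
one per single other compartment, "combination" for more than one, and
leaf-only — plus the mean relative-abundance share the shared ASVs hold in
leaf samples within the cluster's time frame. Time frames default to the
maximal contiguous day window (containing the peak) where the cluster's
mean relative abundance exceeds its across-days median; they are
reporting parameters and user-overridable. Ubiquity is the number of
distinct trees (within one city or both) where an ASV is present;
shared-taxon fractions between groups (e.g. cities) report
|A∩B| / |A∪B|.

## The synthetic-data generator

The generator emulates a two-city chronosequence: Antwerp with four trees
and ten sampling days (−7, −3, 2, 4, 7, 14, 21, 28, 35, 42 relative to
leaf emergence; three visits in the emergence week), Milan with four trees
and five days; four compartments per tree; two street and two park trees
per city; ~1,500 ASVs in the study-scale preset. Per-sample compositions
are softmax-combined log-weights (feature baseline + compartment affinity
+ city and tree random effects + a temporal kernel for cluster members),
overdispersed with a Dirichlet draw and realised as multinomial counts at
a lognormal depth.

Key default parameters (log-abundance scale unless noted):

| parameter | default | meaning |
|---|---|---|
| general kernel | 2.2 (constant) | abundant at all times, all compartments |
| early kernel | 5.0·exp(−t/5 d) | pioneer bloom dominating the fresh leaf, washed out within ~2 weeks |
| middle kernel | 2.6·exp(−(t−14)²/2·5²) | transient mid-window guild |
| late kernel | 3.6·logistic((t−24)/4 d) on street trees; −6 penalty on park trees | urban, dispersal-limited late arrivals |
| background leaf penalty | 4 | non-successional taxa reach leaves only as a rare tail |
| compartment affinity | ±2 | strong compartment structuring of background taxa |
| tree / city effect SD | 0.2 / 0.4 | moderate host-individual and city effects |
| baseline SD | 1.0 (background), 0.5 (cluster members) | cluster members span a narrower abundance range |
| Dirichlet concentration | 3,000 | compositional overdispersion beyond multinomial noise |
| depth (lognormal median, σ) | leaf 3,000 (1.0); bud 2,800 (1.0); branch 24,000 (0.6); trunk 31,000 (0.6) | bacterial reads per sample |
| chloroplast fraction | 0.80 leaf / 0.78 bud / 0.05 branch / 0.02 trunk | host reads removed by the non-bacterial filter, making leaves depth-poor |
| contamination | 10 external (kit genera) + 5 cross (top-abundance taxa); 3 blanks/city | external load ≈ 60 reads/blank, leakage ≈ 5; externals appear in samples at trace level |

The effect sizes were fixed once, before the validation experiments were
frozen, to realise the design the generator is meant to embody: clearly
separated successional guilds (an early pioneer bloom, a compact
mid-window guild, a street-restricted late wave) on top of realistic
depth heterogeneity, contamination and overdispersion. Presets:
`paper_like` (study scale), `tiny` (desk scale, ≤ 40 samples),
`null_model` (one compartment, 14 weekly time points, equal depths, all
effect sizes zero — an exactly exchangeable null for type-I calibration).

What the generator does **not** emulate: sequence-level errors or chimera
structure, phylogenetic relatedness among ASVs, within-sample spatial
structure, weather-driven covariance between sampling days, or gradual
(non-parametric) successional turnover. Passing recovery tests on these
data therefore demonstrates that the pipeline's inference machinery is
correct and well calibrated under its own assumptions, not that real leaf
communities contain exactly four clusters or that support values on real
data will be as high.

## Validation experiment sizes

The validation suite (also run by `scripts/acceptance.py`) uses: 20
exhaustive-enumeration instances (n ≤ 8) for the PERMANOVA oracle; 200
random series (n ≤ 50) for the Kendall oracle and 25 instances (n ≤ 8)
for the Ward oracle; 500 null data sets × 999 permutations for type-I
calibration; 20 study-scale seeds × 100 rarefaction replicates for
cluster recovery; 100 seeds for dynamics recovery; 100 desk-scale seeds
for decontamination recovery; 10 seeds for the overlap/ubiquity contrast.
These sizes are the package's chosen trade-off between Monte-Carlo
precision and a validation run that completes in a few minutes.

## Known limitations

* PERMDISP2 retains a slight liberal tendency at small group sizes even
  with residual permutation (distances within a group share an estimated
  centroid); this matches the reference implementation's behaviour.
* The overlapping consecutive-dissimilarity series is serially dependent;
  its trend p-values are descriptive rather than exactly calibrated (see
  above for the calibrated disjoint variant).
* Rule-based decontamination cannot reproduce unrecorded manual judgement;
  the whitelist/blacklist hooks and review flags exist precisely so a user
  can impose theirs.
* IndVal on shifted CLR values is one of two defensible readings of
  combining a compositional transform with indicator analysis; both modes
  are exposed and results should be compared.
* Sequential (Type-I) PERMANOVA R² values depend on term order; the
  reported decomposition is conditional on the declared order.
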