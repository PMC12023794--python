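# Methods

This note documents the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Synthetic data model

The generator produces the tables a comparative-genomics study of
host-associated bacteria consumes, with known ground truth.

**Phylogeny.** A pure-birth (Yule) tree with `birth_rate` splits per lineage
per unit time, conditioned on `n_tips` extant tips, then extended by one
further exponential waiting time so terminal branches are strictly positive.
Trees are ultrametric by construction and byte-identical under a fixed seed.
For clustering stress tests, `simulate_clade_tree` instead grafts k Yule
subtrees (each rescaled to unit height) onto stems long enough that the
between-clade cophenetic distance exceeds the within-clade maximum by a
configurable ratio; plain Yule trees carry no such guarantee.

**Habitats.** `random` mode assigns balanced labels exchangeably with
respect to the tree. `clade_confounded` cuts the ultrametric tree at the
depth crossed by exactly `n_habitats` lineages (equivalently at its
n_habitats − 1 shallowest internal nodes), making each habitat a clade —
maximal collinearity of phylogeny and habitat, the worst case the
phylogenetic regression must survive.

**Gene counts.** For gene g and genome i,

    count[g, i] ~ Poisson(exp(mu_g + b_i^(g) + effect[g, habitat(i)]))

with b^(g) an independent Brownian-motion realization on the tree
(variance `bm_sigma2` per unit branch length). Defaults: 150 genomes, five
habitats, 200 genes, baseline mean 5 copies (log 5), `bm_sigma2 = 0.2` —
moderate phylogenetic signal relative to Poisson noise, chosen to resemble
ortholog-count dispersion in bacterial pangenomes at this sample size.
Per-gene baseline overrides support rare accessory genes whose signal is in
presence/absence rather than copy number. The generative model is a
deliberate simplification: real ortholog counts are not Poisson and real
habitat effects are not additive on the log mean, so passing recovery tests
demonstrates correctness of the estimators under this model, not biological
fidelity. No sequences or reads are simulated; the pipeline starts at
annotation tables.

**Designed failures and clones.** QC failures are planted on disjoint
genomes, one rule each, drawn inside the failing range (e.g., completeness
uniform on [85, 94.9]). Near-clones are grafted as sister tips (branch 1e-6),
copy their source's count column with at most 0.1% of entries perturbed by
one copy, and receive ANI/AF draws strictly above both redundancy
thresholds, so deduplication is the only mechanism that can remove them.

## Curation conventions

Thresholds follow strict-inequality wording on the failing side: a genome at
exactly 95% completeness, 5% contamination, 83/92 markers, or 85% coding
passes; an ANI pair at exactly 99.995% is not redundant. 90% of 92 markers
is ceiled to 83 because gene tallies are integers. Rules are applied in a
fixed order (site → completeness → contamination → single-copy → coding →
subsample → dedup) so each removal has exactly one attributed cause and the
report always reconciles with the input size. Redundancy is resolved on
connected components of the pair graph rather than pairwise, because random
pairwise removal over chains (A~B, B~C) is order-dependent; one member per
component is kept uniformly at random under the seed.

## Clustering

Cophenetic (patristic) distances feed scipy's agglomerative clustering,
complete linkage by default (average and single are exposed); equal-merge
ties are resolved by scipy's deterministic internal ordering. Silhouettes
use the standard convention s(i) = 0 for singleton clusters; k is chosen to
maximize the mean silhouette. The gap statistic is reported for diagnostics
only: its reference distribution is uniform resampling over the bounding box
of a PCoA embedding, a pragmatic choice since distance-only input admits no
canonical null.

## Phylogenetic linear model

Traits are per-gene standardized copy numbers (population sd; sample sd
optional) or log(count + 0.5) when effects are needed on the additive log
scale. The model is generalized least squares with covariance
V(λ) = λ·V + (1 − λ)·diag(V), V the Brownian matrix of shared root-to-tip
path lengths. All solves whiten through the Cholesky factor of V(λ); no
explicit inverse is formed, and a batch path factors V(λ) once per λ to fit
hundreds of genes at one decomposition cost. λ = 1 (pure Brownian motion) is
the default; `ml` mode maximizes the Gaussian likelihood on a 21-point grid
over [0, 1]. Grid ML matters for Poisson-derived traits: sampling noise adds
an independent diagonal component that pure Brownian covariance does not
model, and fixing λ = 1 there inflates type-I error, while λ̂ absorbs the
mixture. Habitats are coded one-vs-rest, one fit per habitat contrast per
gene, matching a per-habitat enrichment/depletion summary; a multi-level
factor fit would be a straightforward variant but is not the default.
Category summaries take medians of per-gene effects within each COG
category; genes without a category map to an "Unknown function" bucket, and
zero-variance genes are excluded and reported rather than fit.

Multiple testing is Benjamini–Hochberg within each habitat contrast across
genes (and across category pairs for the rank-sum comparisons).

## Association

A gene is "present" in a genome when its count ≥ 1 (exposed as
`presence_min`). The habitat association p-value is the upper hypergeometric
tail P(X ≥ k) evaluated through the log survival function, and the reported
score is −log10 p taken directly on the log scale, so extreme associations
do not underflow. The odds ratio uses the Haldane–Anscombe +0.5 correction
only when a cell is zero; its one-sided Fisher p equals the hypergeometric
tail by construction, and tests are one-sided (overrepresentation) by
default. A gene is habitat-specific when either corrected test clears the
threshold. CPT = 1000 × count / habitat genome tally.

## Function profiles

Pathway copy number is the minimum copy count over the pathway's required
genes — zero iff incomplete, and equal to the number of fully stocked
pathway instances otherwise. Frequencies are compared per pathway across
habitats on copy-number categories {0, 1, ≥2} (bin edges configurable, a
presence/absence mode is provided) by Pearson chi-squared without continuity
correction (Yates optional for 2×2), BH-FDR across pathways. Pathways with
nonzero copies in exactly one habitat are flagged exclusive. CAZyme
annotations are kept only with ≥ 2 supporting algorithms (idempotent
filter); family counts roll up to substrates with full counts contributed to
every substrate a family serves, so the rollup over-counts relative to
family totals exactly when the map is not a partition. Guild comparisons use
the two-sided Mann–Whitney U with normal approximation and tie correction.

## Ordination and group comparisons

Bray–Curtis Σ|u−v| / Σ(u+v) on raw ortholog counts; a pair of all-zero
genomes is an error rather than a silent zero. PCoA Gower-centers −½D² and
drops negative-eigenvalue axes (reported in the spectrum; Lingoes-style
correction was considered and left out as the axes are only used for
constrained fits and plots). PERMANOVA uses the standard decomposition
SS_total = Σd²/N, F = (SS_between/(k−1))/(SS_within/(N−k)), with the
permutation p including the observed labeling — p ≥ 1/(n_perm + 1), so a
fully separated design reports exactly the floor. An exact mode enumerates
all distinct labelings for small N. dbRDA regresses the PCoA coordinates on
centered group indicators and reports the constrained share of inertia;
PERMANOVA R² and dbRDA R² are both emitted since they answer slightly
different questions. Univariate comparisons (richness, genome size, GC) use
ANOVA plus Tukey HSD (Tukey–Kramer when unbalanced), BH adjustment over the
pairwise p-values, and a compact-letter display built from maximal cliques
of the not-significantly-different graph, which guarantees two groups share
a letter iff their pairwise q ≥ α.

## Validation experiments and problem sizes

`fabcomp.validation` fixes the study conditions used by the acceptance
machinery: 200 genomes × 500 Brownian traits for null calibration of the
phylogenetic regression under clade-confounded labels (traits are Gaussian
Brownian realizations because the calibration claim concerns the GLS under
its own null; Poisson nulls are exercised in the association calibration
test instead); 100 seeds × 200 genomes for planted-effect recovery on
log-scale traits; 50 replicate datasets for clone-group deduplication; 200
null datasets (25 genes × 24 genomes, 99 permutations) plus one separated
design (999 permutations) for PERMANOVA calibration; and 100 clade trees
(60 tips, 4 clades, 5:1 separation) for silhouette k-recovery. These sizes
give binomial/Monte-Carlo noise comfortably inside the asserted bands while
keeping a full run in tens of seconds.

## Known limitations

- The Poisson/Brownian generative model is a stand-in; no claim is made that
  it matches the data-generating process of real ortholog tables.
- The phylogenetic regression assumes Gaussian residuals on the (possibly
  standardized) trait scale and a correctly rooted, ultrametric-ish tree;
  λ mitigates but does not remove misspecification.
- One-vs-rest contrasts refit the intercept per habitat and are not a joint
  multi-level model; effects are interpretable per contrast only.
- The gap statistic's uniform-box reference is heuristic; k-selection
  decisions rest on the silhouette.
- Tree inference, annotation, CheckM/BUSCO, and ANI computation are upstream
  of this package and consumed as tables.
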