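# fabcomp

Comparative genomics of fungus-associated bacteria (FaB): a tested, reusable
implementation of the analysis chain used to ask what distinguishes the
genomes of bacteria living with fungi from those of bacteria in plants,
humans, soil, and water.

The pipeline covers six stages, each usable on its own:

1. **Curation** — five-rule genome filtration (isolation site known,
   completeness ≥ 95%, contamination ≤ 5%, ≥ 83 of 92 single-copy marker
   genes, protein-coding fraction ≥ 85%), subsampling to at most 5 genomes
   per species and habitat, and ANI-based deduplication (redundant when
   ANI > 99.995% and alignment fraction > 90%, one random representative per
   redundancy group).
2. **Clustering** — cophenetic distances from the genome phylogeny,
   agglomerative clustering, and silhouette/gap selection of the taxon count.
3. **Enrichment** — per-gene phylogenetic linear regression of standardized
   ortholog copy numbers on habitat membership.  With Brownian-motion
   covariance V from the tree and Pagel's λ,

       V(λ) = λ·V + (1 − λ)·diag(V)
       β̂   = (Xᵀ V(λ)⁻¹ X)⁻¹ Xᵀ V(λ)⁻¹ y

   solved by Cholesky whitening, with t-tests on n − p degrees of freedom,
   BH-FDR across genes, and COG-category median summaries.  λ is fixed at 1
   (pure Brownian motion) or estimated by grid maximum likelihood.
4. **Association** — upper-tail hypergeometric tests and odds ratios on gene
   presence/absence per habitat, −log10 p "hypergeometric scores", CPT
   (counts per thousand genomes) normalization, and habitat-specific gene
   calls by the either-test FDR rule.
5. **Function profiles** — complete-pathway copy numbers (minimum copy count
   over a pathway's required genes, zero if any gene is absent) compared
   across habitats by chi-squared with FDR; CAZyme annotations filtered to
   ≥ 2 supporting algorithms, collated by family, rolled up to substrates,
   and compared between ectomycorrhizal- and saprotrophic-host guilds by
   rank-sum tests.
6. **Ordination** — Bray–Curtis dissimilarity over ortholog counts, PCoA,
   PERMANOVA and distance-based RDA on habitat/host labels, and ANOVA +
   Tukey HSD comparisons (richness, genome size, GC content) with
   compact-letter displays.

Because the original genome collection is external, the package ships a
first-class synthetic-data generator (`fabcomp.synthetic`) that emulates
every input table — ultrametric Yule phylogeny, Poisson ortholog counts with
Brownian phylogenetic signal and planted habitat effects, QC metadata with
designed failures, injected near-clone pairs, CAZyme annotations and pathway
content — with all planted signals recorded in a truth object, so every
stage is testable end to end.

## Worked example

The `analysis/` drivers run the whole chain on a generated 150-genome,
five-habitat collection (12 genes with a planted fungi copy-number
enrichment, 6 rare genes with a planted fungi presence signal, 4 near-clone
pairs, 11 designed QC failures):

```sh
python analysis/01_simulate.py
python analysis/02_curate.py
python analysis/04_enrich.py
python analysis/05_associate.py
```

which prints (abridged):

```
input 154 genomes -> kept 139
  removed by missing_site: 2
  removed by completeness: 3
  ...
  removed by dedup: 4
all planted clone groups collapsed: True

planted fungi-enriched genes recovered at q<0.05: 100%
unplanted genes called in fungi contrast: 5.3%

habitat-specific gene calls:
  fungi: 7 (6 of 6 planted fungi-specific genes)
  humans: 0
  ...
```

The curation stage removes exactly the designed failures and one member of
each clone pair; the phylogenetic regression recovers every planted
enrichment at FDR < 0.05 while the false-call rate stays near the nominal
level; and the association stage finds all planted fungi-specific genes.
`analysis/06_profiles.py` flags the planted fungi-exclusive transporter
pathway (chi² = 121.3, q < 1e-20) and stars the plant substrates boosted in
ectomycorrhizal-host genomes; `analysis/07_ordinate.py` reports the
PERMANOVA/dbRDA habitat signal (R² = 0.056, p = 0.001 on this dataset).

The same stages are available as CLI subcommands
(`fabcomp simulate|curate|cluster|enrich|associate|pathways|cazymes|ordinate|run`)
for use on real tables: tab-separated metadata/count/ANI/CAZyme files, a
newick tree, and YAML pathway/substrate configurations.

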