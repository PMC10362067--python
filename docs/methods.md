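# Methods

## The association model

Gene usage is the fraction of B-cell clones in a repertoire whose
rearrangement uses a given germline gene, computed within segment class:
every clone has exactly one V, one D and one J assignment, so V fractions
are normalised over V genes, D over D, J over J.  For each retained gene and
each common variant the package fits two covariate-adjusted models on
pairwise-complete samples:

* linear regression `usage ~ dosage + age + platform` with a two-sided
  t-test on the dosage coefficient, where dosage is the alternate-allele
  count (0/1/2).  Hemizygous calls are encoded 0/2 ("haploid-doubled"): the
  single surviving allele is the sample's entire dosage at the locus.  A
  categorical-only treatment is available for users who prefer not to place
  hemizygotes on the diploid dosage scale;
* ANOVA with genotype as an unordered categorical factor (an F-test of the
  genotype dummies over the covariate-only model), the multi-allelic-capable
  test, applied to SNVs, complex SVs and mSVs.

The significance gate uses the regression p for biallelic variants and the
ANOVA p for multi-allelic ones; both are always reported.  Genotype classes
observed in fewer than 3 samples are dropped from a variant's test and from
the fold-change groups — the generalisation of excluding the rare 3-copy
duplication haplotype carriers from the copy-number series.  Hemizygous
samples form their own genotype classes in the ANOVA and stratify with the
matching homozygote in conditional scans.

**Multiple testing.**  Bonferroni at the family-wise level α = 0.05 with the
effective test count equal to the number of perfect-LD variant groups:
variants with pairwise r² = 1 carry identical information and represent one
test.  Groups are the transitive closure of the r² ≥ threshold relation
(for exact r² = 1 the relation is transitive, so closure and clique
semantics coincide); multi-allelic variants, which have no scalar dosage,
count as singleton groups.  One global threshold is shared by all genes; a
per-gene effective count is available via the `genes=`/`effective_tests=`
arguments.

**Variance explained.**  `r2_adj` is the *incremental adjusted R²* of the
genotype term: the adjusted R² of the full model minus that of the
covariate-only model.  This estimates the usage-variance fraction
attributable to genotype net of age and platform, which is the quantity the
synthetic ground truth can state exactly.

**Fold change** is the ratio of the larger to the smaller homozygote-class
mean usage.  It is infinite when one homozygote class has mean usage 0
(e.g. deletion homozygotes of a deleted gene) and undefined when fewer than
two homozygote classes survive the 3-sample rule.

**Conditional scans.**  For each gene with a significant lead (the left-most
co-lead anchors stratification when several variants tie at r² = 1), the
cohort is restricted in turn to the lead's homozygous-reference and
homozygous-alternate strata.  Strata with fewer than 50 individuals are
skipped and logged.  Within a stratum, variant filtering (MAF ≥ 0.05,
≥ 40 genotyped, HWE ≥ 1e−6) and LD collapsing are recomputed before the
gene is rescanned, so the reported secondary threshold is the stratum's own
Bonferroni gate.

## Variant handling

Genotype calls are diploid allele pairs, hemizygous single alleles (one
chromosome deleted), or missing (both deleted, or not genotyped).  Allele
frequencies count 2 copies per diploid and 1 per hemizygous call.  MAF is
the minor-allele frequency for biallelic variants and 1 − max allele
frequency for multi-allelic ones.  The Hardy–Weinberg exact test conditions
on the observed allele counts and sums the probabilities of heterozygote
counts no more probable than the observed one; hemizygous samples are
excluded, since HWE is a statement about diploid genotype frequencies and
hemizygosity in this locus arises from real deletion haplotypes rather than
genotyping error.  Missing-genotype imputation is deliberately simple: the
default leaves missing calls missing (pairwise-complete analysis), and the
"frequency" policy resamples from the observed genotype distribution with a
fixed seed — never filling positions inside homozygous deletions, where
absence is the genotype.

## The synthetic cohort generator

The generator is the package's study-condition definition, not a fixture.
A `LocusModel` specifies, per haplotype:

* **genes** with per-copy baseline recombination weights (lognormal spread,
  σ = 0.5);
* **SVs** whose alleles map spanned genes to haploid copy numbers; alleles
  flagged `deletes_snvs` remove the spanned sequence, which is what creates
  hemizygous (one deleted haplotype) and missing (two) SNV calls;
* **LD blocks**: each block has a small pool of ancestral haplotypes and
  every simulated chromosome draws one pool haplotype per block
  independently — within-block r² is high (exactly 1 for two-haplotype
  blocks), across-block r² is ~1/n;
* **cis effects**: a variant allele on a haplotype multiplies the target
  gene's weight *on that haplotype*;
* **covariates**: age (uniform 18–75, no effect by default) and a 3-level
  sequencing-platform factor with per-gene multiplicative batch effects
  (lognormal, σ = 0.05, on ~40% of genes).

Per-haplotype weight is `copies × baseline × Π cis multipliers`; the two
haplotypes add; covariate multipliers apply per sample; class-wise
normalisation gives the usage probability vector.  This multiplicative form
is a modeling choice — the observational data it emulates show an additive
relationship between diploid copy number and usage, which additivity across
haplotypes reproduces, while per-haplotype multipliers keep cis effects
strictly cis.  Clones are drawn multinomially per segment class (the V, D
and J of a clone are independent, since only marginal usage is analysed),
with the coding-allele label of each call taken from the originating
haplotype.

The **default model** has 66 genes (46 V, 14 D, 6 J), ~520 SNVs/indels in
42 LD blocks, and three SVs: a deletion spanning six D genes (allele
frequency 0.30), the IGHV3-23/-23D duplication (the reference haplotype
carries both copies; a frequency-0.5 allele deletes IGHV3-23D, so the merged
unit segregates at 2–4 diploid copies), and a 3-allele mSV over
IGHV1-8/IGHV3-9/IGHV3-64D/IGHV5-10-1 (frequencies 0.5/0.3/0.2).  Two
regulatory SNV effects are planted: a 1.6× multiplier on IGHV3-53 (outside
any SV) and a 1.5× multiplier on IGHD3-3 (inside the deletion SV, so it is
discoverable as a conditional secondary effect within the deletion's
reference-homozygous stratum).  Each effect SNV sits in a dedicated
two-haplotype block with five perfect-LD companions, so lead ties at r² = 1
are a routine occurrence, as in real data.

**Calibration.**  The merged duplication unit's per-copy baseline is set so
2-copy homozygotes average 7.4% usage; by construction 3 and 4 copies then
sit near 2·0.074·1.5/(1 + 0.5·0.074·…) ≈ 10.7% and 2t/(1 + t) ≈ 13.8% —
the additive copy-number pattern.  The regulatory-effect target gene is
calibrated to ~3% baseline usage, the scale of the genes such cis effects
concern; at much lower usage the multinomial sampling noise of a ~9,000-
clone repertoire would dominate the genotype signal.  Cohort size defaults
to n = 150 and clone numbers to Poisson with mean 9,000 per repertoire.

**Ground truth.**  `true_r2(gene, variant)` is the squared correlation of
the noise-free usage probabilities with dosage, computed on the *analysis
basis* — excluded genes removed, duplicated genes merged, renormalised
within class — because that is the scale on which the scan operates.  Two
optional corrections align the truth with the estimator's estimand: with
`n_clones` the value is attenuated by var(u)/(var(u) + ū(1−ū)/n_clones),
the population R² of the observed (multinomially sampled) usage; with
`adjust_covariates` usage and dosage are first residualised on age and
platform, matching the covariate-adjusted incremental R².

**What the generator does not emulate** — and hence what passing tests do
not establish about real repertoires: somatic hypermutation and clonal
lineage structure; isotype selection (IgM and IgG repertoires are
independent draws from the same probabilities); nucleotide-level sequences
and alignment ambiguity (multi-gene assignments are simulated only as an
option, off by default); population structure and kinship; tandem-repeat
genotyping (tandem-repeat variants enter only as pre-genotyped records);
and realistic LD decay within blocks (most blocks are exactly two ancestral
haplotypes, which makes perfect-LD collapsing highly effective — real data
would collapse far less).

## Numerical and procedural choices

* Exact tests: the HWE test enumerates heterozygote counts in log space and
  normalises; Fisher tests on 2×2 tables use the exact hypergeometric; R×C
  tables are enumerated exactly when the table space is small (≤ 2×10⁵
  candidate row-fillings, total ≤ 200) and otherwise estimated from 10⁵
  seeded draws conditional on the margins, with the method recorded.
* p-values are clamped to ≥ 1e−300; ties at the minimum p are all reported
  as co-leads.
* Coordinates: variant positions are 1-based (VCF convention), feature
  intervals 0-based half-open (BED); a variant at position p overlaps
  [start, end) iff start ≤ p−1 < end.
* Enrichment background = common variants tested but significant for no
  gene; the one-sided alternative is fixed to enrichment, and a
  Benjamini–Hochberg column is emitted for reference only.
* ASD at one locus is 2 − |multiset intersection of the allele pairs|,
  averaged over pairwise-complete diploid loci and divided by 2; hemizygous
  and missing loci are skipped.  Pair binning is by ASD rank quantiles
  (4 bins by default) and the extreme bins are compared with a two-sample
  KS test.  The KS test treats the ~n²/2 pair correlations as independent,
  which they are not (each sample participates in n−1 pairs); this mirrors
  the analysis the package reproduces and is a known caveat — under a
  genotype-independent null the KS p-values are anti-conservative, so the
  comparison should be read as descriptive, not calibrated.
* Pipeline determinism: a master seed is split into per-stage child streams
  via `numpy.random.SeedSequence` spawn keys, so stages are independently
  reproducible.

## Problem sizes

The test suite and the acceptance script use the default study conditions:
cohorts of 150 individuals with ~9,000 clones per repertoire; 20 seeds for
recovery and conditional-recovery rates; 20 null cohorts of 200 genes ×
~500 variants for type-I calibration; 50 replicates for the null ASD
comparison; 100 random instances per brute-force oracle check.  The full
suite runs in a few minutes on one CPU.

## Known limitations

The default locus model is a caricature of IGH: gene order and spacing are
schematic, block boundaries are hard, and SV allele frequencies are chosen
for well-populated genotype classes at n = 150 rather than estimated from a
population.  The conditional scan conditions by stratification (as in the
analysis it reproduces), not by adding the lead to the model, so it cannot
detect secondaries whose effect exists only in the discarded heterozygotes.
Imputation is a frequency resampler, not a haplotype-aware imputer, and is
off by default.  The mSV's copy-number effect is tested only through the
categorical ANOVA path, so no dosage-scale effect size is reported for it.
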