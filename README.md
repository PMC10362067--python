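# guqtl — gene-usage QTL mapping of the human IGH locus

The immunoglobulin heavy chain (IGH) locus is one of the most structurally
complex regions of the human genome: its V, D and J gene segments are
interleaved with large structural variants (SVs) that delete or duplicate
whole genes, so that individuals differ not only in SNVs but in diploid gene
copy number, and SNVs inside heterozygous deletions are *hemizygous*.  Which
germline genes a person's B cells use during V(D)J recombination — the
**gene usage** profile of the expressed antibody repertoire — is strongly
heritable, and germline variants that shift it are **gene-usage QTLs
(guQTLs)**.

`guqtl` implements the full guQTL analysis as a tested, reusable pipeline
for immunogenomics researchers:

* **Variant store** — SNVs, indels, SVs and multi-allelic SVs (mSVs) with
  hemizygosity-aware genotypes; common-variant filters (MAF ≥ 0.05,
  genotyped in ≥ 40 individuals, Hardy–Weinberg exact p ≥ 1e−6); dosage
  encoding (hemizygous calls count 0/2); LD computation and perfect-LD
  (r² = 1) collapsing for multiple-testing correction.
* **Usage quantification** — clone-level AIRR tables → genes × samples
  count matrix with merging of indistinguishable duplicated genes
  (IGHV3-23/-23D, IGHV3-30/-30-3/-30-5/-33, IGHV1-69/-69D, IGHD4-4/4-11),
  removal of genes deleted from both chromosomes, per-isotype QC
  (≥ 100 reads, ≥ 200 clones), and class-normalised usage fractions.
* **Association core** — per gene × variant linear regression
  (usage ~ dosage + age + platform) and ANOVA with categorical genotype;
  Bonferroni gate α / (number of perfect-LD groups); lead-variant
  summaries with fold change and incremental adjusted R²; conditional
  scans inside homozygous lead strata (≥ 50 individuals).
* **Networks** — gene graph weighted by shared significant variants,
  maximal cliques after pruning edges with weight ≤ 2.
* **Enrichment** — one-sided Fisher exact overlap of guQTL SNVs with
  regulatory intervals (cCRE/TFBS BED tracks) and GWAS-catalog variants
  (p < 4e−6).
* **Repertoire similarity** — allele sharing distance (ASD) over guQTL
  genotypes vs pairwise Pearson correlation of usage profiles, with
  quantile-bin KS comparison.
* **Synthetic cohort generator** — a fully specified diploid locus model
  (SV alleles with per-gene copy maps, LD-block haplotype pools,
  multiplicative cis effects, covariate batch effects, multinomial clone
  sampling) so every stage is testable with known ground truth.

The central quantity is, for gene *g* and sample *s*,
`u[g,s] = C'[g,s] / Σ_g C'[g,s]` (fraction of clones using *g* within its
segment class), tested against alt-allele dosage with
`u ~ β·dosage + age + platform`; significance requires
`p < α / m_eff`, where `m_eff` counts LD groups with r² = 1 treated as a
single test.

## Worked example

Simulate the default cohort (150 individuals; a D-region deletion SV, the
IGHV3-23/-23D duplication, a 3-allele mSV, two regulatory SNV effects;
~9,000 clones per repertoire) and scan it:

```python
import pandas as pd
from guqtl import default_model, simulate_haplotypes, run_guqtl
from guqtl.usage import (DEFAULT_MERGE_GROUPS, DEFAULT_EXCLUDED_GENES,
                         merge_map_from_groups, usage_fractions)

model = default_model()
cohort = simulate_haplotypes(model, n_samples=150, seed=1)

merge = merge_map_from_groups(DEFAULT_MERGE_GROUPS)
frames, seg = [], {}
for cls in ("V", "D", "J"):
    counts = cohort.clone_counts(n_clones=9000, seed=1, segment=cls)
    counts = counts.drop(index=[g for g in DEFAULT_EXCLUDED_GENES if g in counts.index])
    counts = counts.groupby([merge.get(g, g) for g in counts.index]).sum()
    frames.append(counts)
    seg.update({g: cls for g in counts.index})
usage = usage_fractions(pd.concat(frames), pd.Series(seg), covariates=cohort.covariates)

genotypes, _ = cohort.genotypes.filter_common()
scan = run_guqtl(usage, genotypes, alpha=0.05)
print(f"effective tests: {scan.effective_tests}, threshold: {scan.threshold:.3g}")
for gene in ("IGHD1-7", "IGHV3-23/3-23D", "IGHV3-53"):
    s = scan.summaries[gene]
    print(f"{gene}: lead={s.lead_variants[0]} p={s.lead_p:.3g} "
          f"R2={s.lead_r2_adj:.2f} fold={s.lead_fold_change:.2f}")
```

prints

```
effective tests: 57, threshold: 0.000877
IGHD1-7: lead=sv_del_D p=2.54e-71 R2=0.89 fold=inf
IGHV3-23/3-23D: lead=sv_dup_V3-23 p=7.46e-115 R2=0.98 fold=1.84
IGHV3-53: lead=snv_reg_A p=2.62e-57 R2=0.80 fold=1.56
```

The deletion SV leads the gene it deletes (`fold=inf`: deletion homozygotes
use the gene 0% of the time); the duplication SV leads the merged
IGHV3-23/-23D unit with a ~1.8-fold usage difference between 4-copy and
2-copy homozygotes; the planted regulatory SNV leads its target gene.  The
519 common variants collapse to 57 effective tests because variants within
an LD block are perfectly correlated.

The same pipeline is available end to end from the shell:

```sh
guqtl all --out run1 --seed 1 --n-samples 150
guqtl simulate --out sim1 --seed 1          # VCF + AIRR TSVs + covariates + truth
```

Each stage writes TSV/CSV tables plus a `manifest.json` recording seeds,
thresholds and per-stage counts; identical config and seed reproduce the
outputs byte for byte.

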