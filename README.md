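# mutload

Mutational-load analysis from polarized SNP genotypes: a reusable pipeline
from a multi-sample VCF (with one outgroup sample) and variant-effect
annotation tables to per-genome load statistics, site-frequency spectra,
private-allele accounting, windowed genomic correlates and a
structural-variant consensus branch — plus a forward Wright–Fisher
simulator that generates every input synthetically.

## What it computes

- **Polarization** — ancestral/derived states against an outgroup sample
  (outgroup-homozygous sites only; het/missing outgroup calls are flagged
  and excluded), after accession (>25 % missing), site (biallelic SNPs
  only) and optional MAF filters, with a deterministic per-site-mode
  imputation stand-in.
- **Functional classification** — SIFT-style and PROVEAN-style tables are
  intersected: a nonsynonymous site is *deleterious* only when its SIFT
  label is in the deleterious class **and** its PROVEAN score is < −2.5;
  remaining nonsynonymous sites are neutral-nonsynonymous.
- **Load statistics** — per-genome derived-site counts per category
  (heterozygotes counted ½), nonsyn/syn and del/neutr ratios,
  Kruskal–Wallis + Dunn (Bonferroni) population comparisons with a
  compact-letter display, 10-bin derived-allele-frequency spectra with
  ADAF and a KS verdict (D<N / D>N / D≈N), private-allele accounting and
  genotype-frequency tables for deleterious sites.
- **Genomic windows** — π and Tajima's D in 10-kb windows, per-window
  relative load in 100-kb windows, genetic-map recombination-rate
  interpolation, sweep-statistic attachment, and high/low top-50 %
  partition Wilcoxon tests.
- **Structural variants** — three-caller ingestion (insertions excluded),
  2-of-3 consensus per accession (starts within 100 bp, length ratio
  ≥ 0.9, minimum 30 bp), cross-accession collapsing, MAF ≥ 0.01 filter,
  outgroup polarization, genic/feature overlap with per-Mb size
  adjustment, load inside vs outside SV-overlapped genes, and
  short/long-read concordance.
- **Simulator** — individual-based diploid Wright–Fisher model with four
  site categories, multiplicative fitness `{1, 1+h·s, 1+s}` at
  deleterious sites, partial selfing, bottlenecks and population splits;
  emits VCF, annotation tables (with optional controlled
  misclassification), gene models, a genetic map, a mock sweep grid and
  three jittered mock SV-caller call sets over planted truth.

## CLI

```sh
mutload run --config config.yaml [--seed N] [--outdir DIR]   # full pipeline
mutload simulate --outdir DIR [--seed N]                     # inputs only
mutload sv --config config.yaml                              # SV branch only
mutload report --outdir DIR                                  # PNG plots
```

Without `--config`, `mutload run` uses a built-in illustrative
domestication scenario (wild → semi-domesticated → domesticated, with
bottlenecks and increasing selfing). A config file looks like:

```yaml
outdir: out
seed: 1
# either a simulate block ...
simulate:
  n_sites: 2000
  n_generations: 120
  sel_coeff: -0.05
  epochs:
    wild:         [{start_gen: 0,  N: 120}]
    domesticated: [{start_gen: 60, N: 15, source_pop: wild}]
  selfing_rate: {wild: 0.1, domesticated: 0.9}
  n_sampled:    {wild: 12, domesticated: 12}
# ... or real inputs:
# inputs:
#   vcf: genotypes.vcf
#   assignment: populations.tsv   # 2 columns + '#outgroup=NAME' header
#   sift: sift.tsv                # chrom pos ref alt region substitution label
#   provean: provean.tsv          # chrom pos score
#   gene_models: genes.gff3
#   genetic_map: map.tsv          # chrom bp cM
#   sweep: sweed.tsv              # chrom position likelihood
#   sv_vcfs: {acc1: {callerA: a1.A.vcf, callerB: a1.B.vcf, callerC: a1.C.vcf}}
thresholds:            # defaults shown
  max_missing: 0.25
  min_maf_snp: 0.001
  sv_min_size: 30
  sv_max_dist: 100
  sv_min_overlap: 0.9
  sv_min_maf: 0.01
  diversity_window: 10000
  load_window: 100000
  alpha: 0.05
```

All report tables are TSV with `#`-prefixed provenance headers (package
version, config hash, seed); identical config + seed gives byte-identical
outputs. Exit codes: 0 ok, 1 validation error, 2 compute error.

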