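# germscreen

Cohort-scale screening for germline variants in autosomal dominant
cancer-predisposition genes.

`germscreen` is for analysts who have a multi-sample germline VCF and a
gene panel and want the population-screening question answered: *which
individuals in this cohort carry a pathogenic or likely pathogenic variant
in a cancer-predisposition gene, and what fraction of the cohort is that?*
It implements the full desk-scale analysis: VCF ingestion and variant
normalization, annotation against pluggable knowledge tables (a
ClinVar-style archive and the 1000 Genomes / ESP / ExAC population
panels), a five-stage variant-collection cascade, an ACMG/AMP evidence
engine, and cohort carrier reporting — plus a seeded synthetic-cohort
generator with exact truth tables for validation.

## The method

Variants are collected per site from the cohort VCF and must pass, in
order:

1. **depth** — minimum read depth among carrier samples ≥ 30X;
2. **panel** — the annotated gene is on the autosomal dominant panel;
3. **functional class** — splicing (canonical ±2), nonsynonymous,
   stop-gain, stop-loss, or frameshift;
4. **ClinVar / MAF** — any ClinVar-present variant passes; a novel variant
   passes only if its maximum minor allele frequency across the three
   population panels is ≤ 0.5%;
5. **Hardy–Weinberg** — the exact conditional test on the cohort genotype
   tallies; sites with p < 10⁻⁶ are removed as genotyping artifacts. With
   *n* genotypes and the rarer allele seen *n<sub>r</sub>* times, the
   probability of *h* heterozygotes under random mating is

   Pr(*h*) = C(*n*; *a*, *h*, *b*) · 2<sup>*h*</sup> / C(2*n*, *n<sub>r</sub>*),  *a* = (*n<sub>r</sub>* − *h*)/2,  *b* = *n* − *h* − *a*,

   and the two-sided p-value sums Pr(*h*) over all configurations no more
   probable than the observed one. A singleton heterozygote — the genotype
   signature of a real rare dominant variant — always scores p = 1, so true
   findings cannot be lost at this stage.

Survivors are classified on the five ACMG/AMP tiers (pathogenic, likely
pathogenic, uncertain significance, likely benign, benign). The automatic
step assigns PVS1 (null variant — stop-gain, frameshift, canonical splice —
in a gene where loss of function is an established disease mechanism) and
PM2 (absent from all population panels); literature-dependent codes enter
through a curated manual-evidence table, and the published combining rules
(PVS1 + ≥1 PS → pathogenic; PVS1 + 1 PM → likely pathogenic; BA1 → benign;
…) produce the tier. A sample is a **carrier** if it holds ≥ 1 alternate
allele at ≥ 1 pathogenic or likely pathogenic variant.

## Worked example

```bash
python examples/screen_cohort.py
```

generates the default synthetic cohort — 300 samples, five known
pathogenic variants each planted as a single heterozygote in a distinct
individual, and 35 decoys spanning every filter-failure mode — and screens
it:

```
samples screened:          300
variants in VCF:           40
retained after filters:    15
tier tallies:              {'benign': 5, 'likely_benign': 0, 'likely_pathogenic': 0, 'pathogenic': 5, 'uncertain': 5}
carriers (P/LP variants):  5 (1.7% of cohort)

pathogenic / likely pathogenic findings:
  APC    5:112102976 p.Ser104Ter     pathogenic (rule P-i, codes PM2,PS1,PVS1, Homs/Hets 0/1)
  BRCA2  13:32913729 p.Ser1746Alafs  pathogenic (rule P-i, codes PM2,PS1,PVS1, Homs/Hets 0/1)
  TP53   17:7578389 p.Arg181Cys     pathogenic (rule P-ii, codes PM2,PS1,PS3, Homs/Hets 0/1)
  NF1    17:29679366 p.Arg2496Ter    pathogenic (rule P-i, codes PM2,PS1,PVS1, Homs/Hets 0/1)
  BRCA1  17:41246018 p.Gly511Alafs   pathogenic (rule P-i, codes PM2,PS1,PVS1, Homs/Hets 0/1)
```

The 25 decoys built to fail do fail (five per stage: low depth, off-panel,
wrong functional class, too-common novel variant, Hardy–Weinberg
violation); the ten retained decoys classify benign (BA1) or uncertain;
the five planted variants are recovered, each with one heterozygous
carrier (`Homs/Hets 0/1`), giving 5/300 = 1.7% of the cohort carrying an
actionable finding. The other examples demonstrate the generator
(`simulate_cohort.py`), the evidence combiner (`classify_evidence.py`),
and the Hardy–Weinberg filter (`hwe_filter.py`).

The same pipeline runs from the shell:

```bash
germscreen simulate --seed 1 --out-dir cohort/
germscreen run --vcf cohort/cohort.vcf --panel cohort/panel.tsv \
    --knowledge cohort/knowledge.tsv --gene-model cohort/gene_model.tsv \
    --manual-evidence cohort/manual_evidence.tsv --out-dir screen/
```

writing `variant_report.tsv`, `filter_trace.tsv` (the per-variant failure
audit), `summary.json`, and a reproducibility manifest.

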