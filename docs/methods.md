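# Methods

## Scope and model

`germscreen` answers a population-screening question over a germline
cohort: the fraction of individuals carrying at least one pathogenic or
likely pathogenic variant in a panel of autosomal dominant
cancer-predisposition genes. The analysis is deliberately desk-scale: all
tables are in memory, annotation is a join against user-supplied knowledge
fixtures rather than a live annotator, and the statistical machinery (the
exact Hardy–Weinberg test, the ACMG/AMP combining rules) is implemented
from first principles and property-tested against independent
brute-force oracles.

## Variant representation

Coordinates are 1-based and closed, chromosome labels carry no `chr`
prefix, and every variant is reduced to its minimal representation: the
common suffix of ref/alt is trimmed, then the common prefix (advancing
`pos`), always keeping at least one base per allele — the convention
`bcftools norm` produces. Normalization is idempotent and edit-preserving
(property-tested by applying both representations to a flanked context
sequence). Multiallelic records are split into per-alt sites before
anything else runs; a `1/2` genotype contributes one alternate copy to
each split site. Missing genotypes are excluded from genotype tallies and
Hardy–Weinberg denominators rather than imputed.

## The collection cascade

Five per-variant predicates run in a fixed order (depth → panel → class →
ClinVar/MAF → HWE). Each is pure, so the retained set is order-independent;
the order only fixes which failure a multiply-failing variant is charged
with in the audit trace.

* **Site depth** is the minimum read depth among carrier samples
  (falling back to the minimum over all called samples at carrier-free
  sites). A collection filter cares about the evidence for the variant
  itself, and the variant is only as well supported as its worst-covered
  carrier; a cohort-wide mean would let a poorly covered singleton ride on
  everyone else's coverage. Default threshold 30X, inclusive.
* **Panel** and **functional class** are membership tests; the collected
  classes are splicing, nonsynonymous, stop-gain, stop-loss, frameshift.
  In-frame indels and synonymous changes map to `other` and are excluded.
* **ClinVar/MAF**: presence in the ClinVar-style archive admits a variant
  with no frequency condition; novel variants must have maximum MAF
  ≤ 0.5% (inclusive) across 1000 Genomes, ESP, and ExAC. The ceiling is
  configurable (`novel_maf_max`) because screens are also run at 0.05%.
* **HWE**: variants are removed when p < 10⁻⁶ (retained at exactly the
  threshold; at double precision the distinction between the open and
  closed bound is immaterial).

## The exact Hardy–Weinberg test

The test conditions on the observed allele counts: with `n` genotypes and
the rarer allele seen `rare` times, valid heterozygote counts `h` share
the parity of `rare`, and

    Pr(h) = multinomial(n; a, h, b) * 2^h / C(2n, rare),
    a = (rare - h)/2,  b = n - h - a.

The two-sided p-value sums Pr(h) over all `h` with Pr(h) ≤ Pr(observed).
Probabilities are built by a multiplicative recurrence outward from the
distribution mode and normalized at the end, so no factorials are formed
and the computation is stable far beyond cohort scale (exercised to
n = 10,000 in tests). Ties are compared with a relative tolerance of
1e-12 so configurations that are exactly tied in rational arithmetic are
not split by floating-point rounding. The implementation agrees with an
exact-rational enumeration oracle to ≤ 1e-12 relative error over an
exhaustive sweep of all tallies with n ≤ 60 and 1,000 random tallies at
n = 300. Two structural facts matter for the screen: a monomorphic or
singleton-heterozygote site always scores exactly 1 (a single compatible
configuration), so real rare dominant variants cannot be lost here; and
an extreme heterozygote excess — everyone heterozygous — scores ~10⁻⁸⁹ at
n = 300, far below any sensible threshold.

## Annotation

Annotation is a pure join on the normalized key. Known variants take
their knowledge-table row verbatim (gene, class, HGVS strings, rsID,
ClinVar status, per-panel frequencies); `max_maf` is the maximum over the
frequencies present, 0 when absent from all panels. Novel variants are
classified from a minimal exon/CDS interval model: frameshift from indel
length mod 3 inside coding sequence; splicing within ±2 bases of an
internal exon boundary (transcript ends are not splice sites); coding
SNVs by codon substitution using the model's frame and strand plus
reference bases from an optional region FASTA. Without reference bases a
coding SNV falls back to `nonsynonymous` — the conservative choice, since
it keeps the variant in the collected classes for human review. Codons
spanning exon junctions also fall back to `nonsynonymous`. HGVS strings
are never recomputed; transcript-aware annotation is out of scope and the
knowledge table is the source of record for known variants.

## Evidence engine

The automatic step assigns exactly two codes. PVS1 requires a null
consequence (stop-gain, frameshift, canonical splicing — not stop-loss)
in a gene whose panel entry records loss of function as the disease
mechanism; genes missing from the panel withhold PVS1 with a warning.
PM2 defaults to strict absence (`max_maf == 0`) from all three population
panels; an extreme-rarity threshold is exposed (`pm2_maf_max`) but off by
default. Everything literature-dependent (PS1, PS3, PM5, PP- and B-side
codes) enters through the manual-evidence table, mirroring the
automated-assessment-plus-manual-review split of clinical practice; a
`!`-prefixed code in that table deletes an automatic code, so a reviewer
can veto PVS1 for, say, a terminal-exon truncation.

Combination follows the published 2015 ACMG/AMP rules (pathogenic:
PVS1 + ≥1 PS, or PVS1 + ≥2 PM, …; likely pathogenic: PVS1 + 1 PM, 1 PS +
1–2 PM, …; benign: BA1 or ≥2 BS; likely benign: 1 BS + 1 BP or ≥2 BP).
The pathogenic and benign sides are evaluated independently; if rules fire
on both sides the result is uncertain (`conflict_uncertain`), and with no
rule it is uncertain (`default_uncertain`). The engine is a pure function
of the code set and is verified against an independent brute-force rule
evaluator over every subset of ≤ 4 codes plus 10,000 random larger
subsets. A ClinVar assertion is carried into the report as context but
never overrides the engine — the evidence rules decide.

## Cohort report

Carriers are the union, over pathogenic/likely-pathogenic variants, of
samples with ≥ 1 alternate allele (homozygotes count once toward carrier
status; zygosity is preserved separately in the per-variant `Homs/Hets`
tally). The carrier percentage rounds half away from zero to one decimal,
so 5/300 = 1.666…% prints as 1.7%. Tier tallies are computed over
classified variants, not samples. Outputs are byte-deterministic given
inputs; the run manifest (input checksums, configuration) is the only
file with a timestamp.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, and its
defaults are those conditions: 300 samples; the five core panel variants
(APC p.Ser104Ter, BRCA1 p.Gly511Alafs, BRCA2 p.Ser1746Alafs, NF1
p.Arg2496Ter, TP53 p.Arg181Cys) each planted as one heterozygote in a
distinct uniformly chosen sample and absent from all three population
panels; and five decoys in each of seven categories — sub-threshold
depth, off-panel gene, disallowed class, too-common novel variant,
Hardy–Weinberg violation, common ClinVar-benign, and rare
uncertain-significance variants — so every failure mode and every
non-pathogenic tier is exercised.

Per-call depth is negative-binomial (mean 45, dispersion 10 — a realistic
short-read WGS coverage profile) floored at 10, the calling threshold of
the emulated input. Carriers at sites meant to survive collection are
redrawn conditional on ≥ 30X, and carriers at depth-failure decoys drawn
uniformly on 10–29X, so the depth stage is decided by construction.
Genotypes at the common benign sites are drawn under random mating (so
they pass HWE with overwhelming probability); the HWE-failing decoy is
constructed deterministically (every sample heterozygous) rather than
sampled. Decoy coordinates live in synthetic three-exon gene models
placed near each panel gene's genuine locus, disjoint from the planted
coordinates. Everything is a deterministic function of the seed:
regeneration is byte-identical.

What the generator does **not** emulate: genome-wide variant density
(tens of sites, not millions), linkage disequilibrium, relatedness,
population structure, strand-asymmetric transcripts (synthetic models are
all plus-strand; the minus-strand consequence path is unit-tested
separately), sequencing error, or sex chromosomes (the panel is
autosomal). Passing the recovery tests therefore shows the pipeline's
logic is correct on inputs with the assumed structure, not that the
thresholds are optimal for any particular real cohort.

## Problem sizes and numerical choices

The default validation cohort is 300 samples × 40 sites, chosen to match
the screening design the pipeline models; generation plus a full screen
takes well under a second, and the complete test suite — including the
exhaustive Hardy–Weinberg sweep (all ~41,000 tallies with n ≤ 60), the
exhaustive ACMG subset sweep, and full truth-table recovery across ten
seeds — runs in a few seconds on one CPU. Thresholds are inclusive as
stated (≥ 30X, ≤ 0.5%); tie handling in the HWE test and the
half-away-from-zero rounding of the carrier percentage are described
above.

## Known limitations

* Annotation is only as good as the supplied knowledge table; novel-variant
  consequence calls use a minimal gene model, not transcript-aware HGVS.
* Only PVS1 and PM2 are automated; a screen without a curated
  manual-evidence table will classify most true positives likely
  pathogenic (PVS1 + PM2) at best and missense variants uncertain.
* The HWE test assumes one homogeneous randomly mating population;
  stratified cohorts can produce legitimate heterozygote deficits that
  this filter would not flag and artifacts it might miss.
* No structural variants, no gVCF handling, no somatic analysis.
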