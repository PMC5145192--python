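"""Generate a synthetic screening cohort and inspect its truth table.

Builds a seeded 300-sample cohort VCF in which five known pathogenic
variants are each carried heterozygously by one individual, surrounded by
decoy variants covering every filter-failure mode, and prints what was
planted where.  The truth table is the exact answer key the pipeline is
expected to recover.
"""

from pathlib import Path

from germscreen import SimulationConfig, generate

out_dir = Path("scratch/example_cohort")
sim = generate(SimulationConfig(seed=1), out_dir)

print(f"wrote {sim.vcf} plus fixture tables to {out_dir}/")
print("\nplanted pathogenic variants (one heterozygous carrier each):")
for row in sim.truth.planted:
    print(f"  {str(row.key):32s} carrier {row.carrier_sample} ({row.zygosity})")

print("\ndecoy variants per intended outcome:")
categories: dict[str, int] = {}
for row in sim.truth.decoys:
    categories[row.category] = categories.get(row.category, 0) + 1
for category, count in sorted(categories.items()):
    print(f"  {category:12s} {count}")
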