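"""The exact Hardy-Weinberg test as a genotyping-artifact filter.

The test conditions on the observed allele counts and asks how probable
the observed heterozygote count is under random mating.  Real rare
germline variants (singleton heterozygotes) always score p = 1 and can
never be removed; a site where far too many samples are heterozygous — the
classic signature of a mapping or calling artifact — scores astronomically
low and is filtered at the 1e-6 threshold.
"""

from germscreen import hwe_exact_test

tallies = [
    (299, 1, 0),    # singleton heterozygote: the planted-variant genotype
    (25, 50, 25),   # exactly the random-mating expectation
    (270, 28, 2),   # unremarkable polymorphic site
    (150, 150, 0),  # marked heterozygote excess
    (0, 300, 0),    # every sample heterozygous: artifact signature
]

threshold = 1e-6
print(f"{'homref':>7s} {'het':>5s} {'homalt':>7s}   {'p':>12s}   verdict")
for a, h, b in tallies:
    p = hwe_exact_test(a, h, b)
    verdict = "filtered" if p < threshold else "kept"
    print(f"{a:7d} {h:5d} {b:7d}   {p:12.4g}   {verdict}")
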