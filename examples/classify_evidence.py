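"""Combine ACMG/AMP evidence codes into five-tier classifications.

Shows the combining rules directly: each line is a set of evidence codes
and the tier the engine derives, with the combining rule that fired.
PVS1 = null variant in a loss-of-function disease gene, PS* = strong,
PM* = moderate, PP* = supporting pathogenic evidence; BA1/BS*/BP* are the
benign-side counterparts.
"""

from germscreen import EvidenceProfile, VariantKey, combine_evidence

key = VariantKey("17", 41246018, "TG", "T")

examples = [
    {"PVS1", "PS1", "PM2"},   # truncating, previously reported, absent from controls
    {"PVS1", "PM2"},          # truncating and absent, no literature support
    {"PS1", "PS3"},           # reported in patients + functional deficiency
    {"PM2"},                  # merely absent from population panels
    {"BA1"},                  # too common in controls to cause a dominant syndrome
    {"BS1", "BP4"},           # benign-leaning frequency + in-silico evidence
    {"PVS1", "PM2", "BA1"},   # contradictory evidence on both sides
    set(),                    # no evidence at all
]

for codes in examples:
    profile = EvidenceProfile(key=key, codes=frozenset(codes))
    result = combine_evidence(profile)
    shown = ",".join(sorted(codes)) or "(none)"
    print(f"{shown:20s} -> {result.tier.value:18s} rule {result.rule_fired}")
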