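# Manual-review evidence for the five core variants, encoding a certified
# geneticist's literature assessment as ACMG/AMP codes:
#   - truncating variants previously reported in affected patients -> PS1
#   - the TP53 missense: reported in affected carriers from multiple
#     unrelated families (PS1) and functionally deficient in published
#     assays (PS3)
# A "!" prefix would delete an automatically assigned code.
chrom	pos	ref	alt	codes
5	112102976	C	G	PS1
17	41246018	TG	T	PS1
13	32913729	A	AT	PS1
17	29679366	C	T	PS1
17	7578389	G	A	PS1,PS3
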