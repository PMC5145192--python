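# Knowledge-base fixture for the five core pathogenic/likely-pathogenic
# variants (emulating a ClinVar + 1000 Genomes + ESP + ExAC lookup).
# Empty frequency fields mean the variant is absent from that panel.
# Note: the rsID for the APC variant is reported inconsistently in public
# sources (rs72953290 vs rs74953290); this table uses rs74953290.
chrom	pos	ref	alt	gene	func	aa_change	cdna_change	rsid	clinvar_present	clinvar_assertion	maf_1000g	maf_esp	maf_exac
5	112102976	C	G	APC	stop_gain	p.Ser104Ter	c.311C>G	rs74953290	true	pathogenic		
17	41246018	TG	T	BRCA1	frameshift	p.Gly511Alafs	c.1530del	rs80357735	true	pathogenic		
13	32913729	A	AT	BRCA2	frameshift	p.Ser1746Alafs	c.5238dupT	rs80359499	true	pathogenic		
17	29679366	C	T	NF1	stop_gain	p.Arg2496Ter	c.7486C>T	rs866445127	true	pathogenic		
17	7578389	G	A	TP53	nonsynonymous	p.Arg181Cys	c.541C>T	rs587782596	true	likely_pathogenic		
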