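# Autosomal dominant cancer-predisposition screening panel.
# lof_mechanism: true when loss of function is an established disease
# mechanism for the gene (gates PVS1); false for activation-mechanism genes.
symbol	lof_mechanism
APC	true
BRCA1	true
BRCA2	true
NF1	true
TP53	true
MLH1	true
MSH2	true
MSH6	true
PMS2	true
PTEN	true
RB1	true
VHL	true
CDH1	true
STK11	true
PALB2	true
SMAD4	true
BMPR1A	true
MEN1	true
RET	false
CDK4	false
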