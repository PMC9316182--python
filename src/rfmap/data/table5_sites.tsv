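# Coding variant sites of the four candidate genes, located by 1-based
# CDS offset.  cms_allele is the CMS-line (HZ1A) base, restorer_allele
# the restorer-line (HZ1C) base.  The 318 bp site removes the restorer
# haplotype's stop codon (TGA -> TGG) in the CMS haplotype, so it is
# classed as a stop-loss rather than a plain missense change.
gene	cds_offset	cms_allele	restorer_allele	consequence
Capana06g002965	129	A	C	missense
Capana06g002965	436	T	C	synonymous
Capana06g002965	504	G	A	missense
Capana06g002967	935	G	A	missense
Capana06g002968	20	G	C	missense
Capana06g002968	467	T	G	missense
Capana06g002969	144	G	A	synonymous
Capana06g002969	196	T	G	missense
Capana06g002969	318	G	A	stop_loss
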