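# Allele calls of the CMS, restorer, maintainer and additional restorer
# lines at the nine coding variant sites (columns are gene:cds_offset).
line	role	Capana06g002965:129	Capana06g002965:436	Capana06g002965:504	Capana06g002967:935	Capana06g002968:20	Capana06g002968:467	Capana06g002969:144	Capana06g002969:196	Capana06g002969:318
HZ1A	CMS line	A	T	G	G	G	T	G	T	G
HZ1C	Restorer line	C	C	A	A	C	G	A	G	A
P21204	Maintainer line	C	T	G	G	G	G	G	G	G
P21238	Maintainer line	A	T	G	A	G	T	A	T	G
P21239	Maintainer line	A	T	G	A	G	T	A	T	G
P21241	Maintainer line	A	T	G	A	G	T	A	T	G
P21243	Maintainer line	A	T	G	A	G	T	A	T	G
P21244	Maintainer line	A	T	G	A	G	T	A	T	G
P21246	Maintainer line	A	T	G	A	G	T	A	T	G
P21270	Maintainer line	A	T	G	A	G	T	A	T	G
P21273	Maintainer line	A	T	G	A	G	T	A	T	G
P21215	Restorer line	A	T	G	A	C	G	A	G	A
P21240	Restorer line	A	T	G	A	C	G	A	G	A
P21247	Restorer line	A	T	G	A	C	G	A	G	A
P21274	Restorer line	A	T	G	A	G	T	A	T	G
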