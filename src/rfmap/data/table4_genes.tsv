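# Annotated genes in the mapped interval (Zunla-1 V2.0 gene models).
gene	chromosome	start	end	description
Capana06g002965	Chr06	215102194	215102754	Unknown protein
Capana06g002967	Chr06	215172352	215173332	CW-type zinc finger protein
Capana06g002968	Chr06	215328827	215334970	Tetratricopeptide repeat protein
Capana06g002969	Chr06	215340394	215341013	Unknown protein
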