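# Fine-mapping screen: recombinant tallies over 336 sterile F2 plants.
# Only heterozygous (HE) recombinants were reported at this stage; HO
# counts default to 0.  printed_d_cm is the published Kosambi distance.
marker	chromosome	position	class	n_ho	n_he	n_total	printed_d_cm
P06g8229	Chr06	208899271	SSR	0	43	336	6.43
P06g8335	Chr06	210959629	SSR	0	35	336	5.23
P06g8405	Chr06	212732234	SSR	0	24	336	3.58
P06g8434	Chr06	213257869	SSR	0	23	336	3.43
P06g8219	Chr06	208736376	SSR	0	22	336	3.28
P06gInDel-15	Chr06	213906630	InDel	0	20	336	2.98
P06g8528	Chr06	215338579	SSR	0	6	336	0.89
P06gInDel-38	Chr06	214431109	InDel	0	4	336	0.60
P06g8490	Chr06	214353887	SSR	0	4	336	0.60
P06g8499	Chr06	214498896	SSR	0	4	336	0.60
P06g8508	Chr06	214872305	SSR	0	3	336	0.45
P06gInDel-46	Chr06	214885975	InDel	0	2	336	0.30
P06gInDel-48	Chr06	214903798	InDel	0	2	336	0.30
P06gInDel-56	Chr06	214950959	InDel	0	2	336	0.30
P06gInDel-66	Chr06	215097259	InDel	0	1	336	0.15
P06g8527	Chr06	215336423	SSR	0	0	336	0.00
P06gInDel-79	Chr06	215419831	InDel	0	0	336	0.00
P06gInDel-81	Chr06	215498386	InDel	0	0	336	0.00
P06gInDel-89	Chr06	215631069	InDel	0	1	336	0.15
P06gInDel-90	Chr06	215633948	InDel	0	1	336	0.15
P06gInDel-91	Chr06	215636889	InDel	0	2	336	0.30
P06gInDel-92	Chr06	215669032	InDel	0	2	336	0.30
P06gInDel-94	Chr06	215669384	InDel	0	2	336	0.30
P06gInDel-95	Chr06	215674072	InDel	0	2	336	0.30
P06g8543	Chr06	215710422	SSR	0	3	336	0.45
P06gInDel-99	Chr06	215741617	InDel	0	3	336	0.45
P06g8549	Chr06	215773438	SSR	0	3	336	0.45
P06g8560	Chr06	215995331	SSR	0	6	336	0.89
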