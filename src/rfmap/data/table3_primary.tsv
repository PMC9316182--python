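# Primary mapping screen: recombinant tallies over 45 sterile F2 plants.
# printed_d_cm is the published Kosambi distance, kept for cross-checking.
marker	chromosome	position	class	n_ho	n_he	n_total	printed_d_cm
P06g8405	Chr06	203656182	SSR	3	0	45	6.71
P06g8089	Chr06	204569609	SSR	2	0	45	4.46
P06g8229	Chr06	208899271	SSR	0	2	45	2.22
P06g8264	Chr06	209767667	SSR	0	0	45	0.00
P06g8077	Chr06	212732221	SSR	2	1	45	5.58
P06g8490	Chr06	214353887	SSR	0	0	45	0.00
P06g8494	Chr06	214428701	SSR	0	0	45	0.00
P06g8497	Chr06	214494826	SSR	0	0	45	0.00
P06g8527	Chr06	215336423	SSR	0	0	45	0.00
P06g8536	Chr06	215672797	SSR	0	0	45	0.00
P06g8560	Chr06	215995316	SSR	0	1	45	1.11
P06g8618	Chr06	216556879	SSR	2	0	45	4.46
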