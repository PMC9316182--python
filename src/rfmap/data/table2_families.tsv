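# F2 fertile/sterile segregation counts per family.
# Note: family P20218 lists a printed total (97) that disagrees with the
# component sum (65 + 22 = 87); computations always use the component sum.
family	season	printed_total	n_fertile	n_sterile
P20210	2020 Autumn	66	53	13
P20217	2020 Autumn	63	53	10
P20218	2020 Autumn	97	65	22
P211014	2021 Spring	134	102	32
P211017	2021 Spring	370	279	91
P211091	2021 Spring	129	102	27
P211103	2021 Spring	168	134	34
P211115	2021 Spring	160	128	32
P211129	2021 Spring	161	121	40
P211157	2021 Spring	218	165	53
P211162	2021 Spring	102	75	27
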