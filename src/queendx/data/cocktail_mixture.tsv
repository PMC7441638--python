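name	mode_of_action	group	median_wax_ppb	concentration_ppb	published_hq
Coumaphos	Acetylcholine esterase inhibitor	acaricide	943	3145	3.00
tau-Fluvalinate	Sodium channel modulator	acaricide	4310	14373	332.56
2,4-DMPF	Octopamine receptor agonist	metabolite	30.4	101	1.35
Chlorothalonil	Multisite activity	fungicide	36	120	1.08
Chlorpyrifos	Acetylcholine esterase inhibitor	insecticide	2.7	9.0	111.81
Fenpropathrin	Sodium channel modulator	insecticide	16.8	56.0	61.12
Pendimethalin	Inhibition of microtubule assembly	herbicide	5.3	17.7	0.02
Atrazine	Inhibition of photosynthesis	herbicide	5.4	18.0	0.01
Azoxystrobin	Cytochrome bc1 inhibitor	fungicide	5.1	17.0	0.01
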