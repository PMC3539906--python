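name	site	cohesive_end	end_type	dam	dcm
XhoI	CTCGAG	TCGA	five_prime	0	0
XbaI	TCTAGA	CTAG	five_prime	0	0
BamHI	GGATCC	GATC	five_prime	0	0
SalI	GTCGAC	TCGA	five_prime	0	0
EcoRI	GAATTC	AATT	five_prime	0	0
NheI	GCTAGC	CTAG	five_prime	0	0
BclI	TGATCA	GATC	five_prime	1	0
SpeI	ACTAGT	CTAG	five_prime	0	0
SacI	GAGCTC	AGCT	three_prime	0	0
AvrII	CCTAGG	CTAG	five_prime	0	0
NcoI	CCATGG	CATG	five_prime	0	0
PciI	ACATGT	CATG	five_prime	0	0
AhlI	ACTAGT	CTAG	five_prime	0	0
Psp124BI	GAGCTC	AGCT	three_prime	0	0
Ksp22I	TGATCA	GATC	five_prime	1	0
AspA2I	CCTAGG	CTAG	five_prime	0	0
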