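ko_id	symbol	family
K03581	recD	recombination
K03582	recB	recombination
K03583	recC	recombination
K01144	xni	recombination
K14162	DPO3A2	dna_polymerase_iii
K03469	rnhA-dnaQ	dna_polymerase_iii
K02343	DPO3T	dna_polymerase_iii
K02339	DPO3C	dna_polymerase_iii
K02344	DPO3P	dna_polymerase_iii
K02342	DPO3E	dna_polymerase_iii
K02698	priB	primosome
K04067	priC	primosome
K02686	dnaT	primosome
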