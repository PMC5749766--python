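ko_id	symbol	family
K02092	apcA	allophycocyanin
K02093	apcB	allophycocyanin
K02094	apcC	allophycocyanin
K02095	apcD	allophycocyanin
K02096	apcE	allophycocyanin
K02097	apcF	allophycocyanin
K02284	cpcA	phycocyanin
K02285	cpcB	phycocyanin
K02286	cpcC	phycocyanin
K02287	cpcD	phycocyanin
K02288	cpcE	phycocyanin
K02289	cpcF	phycocyanin
K02290	cpcG	phycocyanin
K05376	cpeA	phycoerythrin
K05377	cpeB	phycoerythrin
K05378	cpeC	phycoerythrin
K05379	cpeD	phycoerythrin
K05380	cpeE	phycoerythrin
K05381	cpeR	phycoerythrin
K05382	cpeS	phycoerythrin
K05383	cpeT	phycoerythrin
K05384	cpeU	phycoerythrin
K05385	cpeY	phycoerythrin
K05386	cpeZ	phycoerythrin
K05337	pebA	phycoerythrobilin
K05338	pebB	phycoerythrobilin
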