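chrM	63	64	HS
chrM	151	152	HS
chrM	194	195	HS
chrM	513	514	HS
chrM	16092	16093	HS
chrM	16188	16189	HS
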