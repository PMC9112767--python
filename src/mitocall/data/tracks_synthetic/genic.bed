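chrM	16023	16569	Dloop
chrM	0	576	Dloop
chrM	3306	4262	CDS:MT-ND1
chrM	4469	5511	CDS:MT-ND2
chrM	5903	7445	CDS:MT-CO1
chrM	7585	8269	CDS:MT-CO2
chrM	8365	8572	CDS:MT-ATP8
chrM	8526	9207	CDS:MT-ATP6
chrM	9207	9990	CDS:MT-CO3
chrM	10058	10404	CDS:MT-ND3
chrM	10469	10766	CDS:MT-ND4L
chrM	10766	12137	CDS:MT-ND4
chrM	12336	14148	CDS:MT-ND5
chrM	14148	14673	CDS:MT-ND6
chrM	14746	15887	CDS:MT-CYB
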