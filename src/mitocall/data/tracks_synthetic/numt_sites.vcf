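##fileformat=VCFv4.2
##source=mitocall-synthetic-numt
##contig=<ID=chrM,length=16569>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chrM	2706	.	A	G	.	PASS	.
chrM	7028	.	C	T	.	PASS	.
chrM	8701	.	A	G	.	PASS	.
chrM	10398	.	A	G	.	PASS	.
chrM	11719	.	G	A	.	PASS	.
chrM	12612	.	G	A	.	PASS	.
chrM	12705	.	C	T	.	PASS	.
chrM	16093	.	T	C	.	PASS	.
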