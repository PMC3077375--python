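Chromosome	Position	Gene	Ref. Gen.	Consensus Genome	1st Best Base	1st Best Freq.	2nd Best Base	2nd Best Freq.	HEF19 Genome	hFL24 Genome	Expression dhFL24-HEF19
1	25589895	RHCE	G	G/C	C	53\82	G	28\82	CG	GG	4.62
1	25589952	RHCE	C	G/C	C	40\45	G	5\45	CC	CG	4.62
1	117968400	FAM46C	C	T/C	T	88\112	C	24\112	CT	TT	5.32
1	117968722	FAM46C	A	G/A	G	87\113	A	26\113	GA	GG	5.32
1	156847383	SPTA1	G	G/A	A	45\72	G	27\72	GA	AA	7.1
1	156947511	SPTA1	T	T/C	T	33\45	C	12\45	TT	CT	7.1
11	33837472	LMO2	T	A/T	T	7\10	A	3\10	TT	AT	2.37
11	33837592	LMO2	T	T/C	C	5\8	T	3\8	CC	TC	2.37
14	36219544	SLC25A21	G	G/A	G	4\7	A	3\7	GA	GG	5.24
17	7501560	ATP1B2	T	G/T	T	14\19	G	3\19	N/A	TT	2.84
17	77092614	ACTG1	G	G/A	G	4\7	A	3\7	GA	AA	-3.82
18	53391503	FECH	C	T/C	C	16\21	T	5\21	TC	CC	3.79
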