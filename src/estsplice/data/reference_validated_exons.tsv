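anatomical_system	gene_id	exon_label	chrom	start	end	length_bp	predicted_specificity
CNS	ATP6V0A1	A	Chr17	37919833	37920004	172	N
CNS	CS	B	Chr12	54971682	54971844	163	T
CNS	METT10D	C	Chr17	2325285	2325343	59	TT
CNS	PCNP	D	Chr3	102786971	102787045	75	NN
CNS	PCNP	E	Chr3	102791749	102791804	56	NN
CNS	STRADA	F	Chr17	59157730	59157787	58	N
CNS	STRADA	G	Chr17	59154390	59154418	29	N
MSK	NAP1L1	H	Chr12	74748956	74749041	86	TT
MSK	NAP1L1	I	Chr12	74747418	74747520	103	TT
MSK	SLC25A3	J	Chr12	97513636	97513757	122	TT
MSK	SLC25A3	K	Chr12	97513342	97513466	125	N
MSK	TPD52L2	L	Chr20	61977613	61977672	60	NN
MSK	TPM3	M	Chr1	152408405	152408483	79	NN
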