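gene_id	tissues	cassette_exons
ACTN1	CNS	N
ALDOA	TES	N
ATP6V0A1	CNS	N
CS	CNS	T
CTNNA1	CNS	N
DCTN1	CNS	N/T
EEF1D	EYE	T
EWSR1	CNS	N
FAM104A	TES	N
FAM49B	CNS	N
GSN	KID	T
HDLBP	CNS	T
HLA-B	RES,LYM,MSK	N/T
HLA-C	LYM,MSK,DER	N/T
HLA-DRB1	CNS	T
HSPA8	DER	T
IARS	CNS	N
IDH3A	LYM	N
ITIH4	LIV	N
LDHA	DER	N
LMNA	DER	T
METT10D	CNS	T
MYL6	PLA	N
MVK	CNS	N
NAP1L1	MSK	T
NDRG4	CNS	N
NRSN2	CNS	N
PCNP	CNS	N
PKM2	TES	N
PLEKHB1	EYE	N
POMT1	TES	T
PRKCZ	PLA	T
RAN	RES	T
RPH3A	CNS	N
RPS24	MSK	N
SELENBP1	CNS	N
SLC25A3	MSK	N/T
STRADA	CNS	N
TMEM87A	CNS	N
TPD52L2	MSK	N
TPM3	MSK	N
UQCC	CNS	N
WARS	LYM	T
YPEL5	CNS	T
ZFAND6	TES	N
ZNF655	CNS	T
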