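# S. cerevisiae cytoplasmic tRNA isoacceptors: nuclear gene copy numbers
# and decoding specificities after Percudani, Pavesi & Ottonello (1997).
# Anticodons are RNA 5'->3'; codons are DNA.  Near-cognate codons pair
# with the anticodon with a single mismatch in codon position 2 or 3
# and exclude codons the species decodes (wobble cognates).
anticodon	amino_acid	gene_copies	cognate_codons	near_cognate_codons
AGC	A	11	GCT,GCC,GCA	GAT,GCG,GGT,GTT
UGC	A	5	GCA,GCG	GAA,GCC,GCT,GGA,GTA
ACG	R	6	CGT,CGC,CGA	CAT,CCT,CGG,CTT
CCG	R	1	CGG	CAG,CCG,CGA,CGC,CGT,CTG
UCU	R	11	AGA	AAA,ACA,AGC,AGG,AGT,ATA
CCU	R	1	AGG	AAG,ACG,AGA,AGC,AGT,ATG
GUU	N	10	AAT,AAC	AAA,AAG,ACC,AGC,ATC
GUC	D	16	GAT,GAC	GAA,GAG,GCC,GGC,GTC
GCA	C	4	TGT,TGC	TAC,TCC,TGG,TTC
UUG	Q	9	CAA	CAC,CAG,CAT,CCA,CGA,CTA
CUG	Q	1	CAG	CAA,CAC,CAT,CCG,CGG,CTG
UUC	E	14	GAA	GAC,GAG,GAT,GCA,GGA,GTA
CUC	E	2	GAG	GAA,GAC,GAT,GCG,GGG,GTG
GCC	G	16	GGT,GGC	GAC,GCC,GGA,GGG,GTC
UCC	G	3	GGA	GAA,GCA,GGC,GGG,GGT,GTA
CCC	G	2	GGG	GAG,GCG,GGA,GGC,GGT,GTG
GUG	H	7	CAT,CAC	CAA,CAG,CCC,CGC,CTC
AAU	I	13	ATT,ATC	AAT,ACT,AGT,ATA,ATG
UAU	I	2	ATA	AAA,ACA,AGA,ATC,ATG,ATT
CAA	L	10	TTG	TCG,TGG,TTA,TTC,TTT
UAA	L	7	TTA	TCA,TTC,TTG,TTT
UAG	L	3	CTA,CTG	CAA,CCA,CGA,CTC,CTT
GAG	L	1	CTT,CTC	CAC,CCC,CGC,CTA,CTG
CUU	K	14	AAG	AAA,AAC,AAT,ACG,AGG,ATG
UUU	K	7	AAA	AAC,AAG,AAT,ACA,AGA,ATA
CAU	M	5	ATG	AAG,ACG,AGG,ATA,ATC,ATT
GAA	F	10	TTT,TTC	TAC,TCC,TGC,TTA,TTG
AGG	P	2	CCT,CCC	CAT,CCA,CCG,CGT,CTT
UGG	P	10	CCA,CCG	CAA,CCC,CCT,CGA,CTA
AGA	S	11	TCT,TCC	TAT,TCA,TCG,TGT,TTT
UGA	S	3	TCA	TCC,TCG,TCT,TTA
CGA	S	1	TCG	TCA,TCC,TCT,TGG,TTG
GCU	S	4	AGT,AGC	AAC,ACC,AGA,AGG,ATC
AGU	T	11	ACT,ACC	AAT,ACA,ACG,AGT,ATT
UGU	T	4	ACA	AAA,ACC,ACG,ACT,AGA,ATA
CGU	T	1	ACG	AAG,ACA,ACC,ACT,AGG,ATG
CCA	W	6	TGG	TCG,TGC,TGT,TTG
GUA	Y	8	TAT,TAC	TCC,TGC,TTC
AAC	V	14	GTT,GTC	GAT,GCT,GGT,GTA,GTG
UAC	V	2	GTA	GAA,GCA,GGA,GTC,GTG,GTT
CAC	V	2	GTG	GAG,GCG,GGG,GTA,GTC,GTT
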