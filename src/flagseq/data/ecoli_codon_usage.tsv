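# Codon usage weights biased toward highly expressed E. coli genes.
# residue<TAB>codon<TAB>weight; rows for a residue are ranked by weight.
A	GCT	0.35
A	GCG	0.30
A	GCA	0.20
A	GCC	0.15
R	CGT	0.45
R	CGC	0.35
R	CGG	0.08
R	CGA	0.06
R	AGA	0.04
R	AGG	0.02
N	AAC	0.60
N	AAT	0.40
D	GAT	0.55
D	GAC	0.45
C	TGC	0.55
C	TGT	0.45
Q	CAG	0.70
Q	CAA	0.30
E	GAA	0.70
E	GAG	0.30
G	GGT	0.40
G	GGC	0.35
G	GGA	0.15
G	GGG	0.10
H	CAC	0.55
H	CAT	0.45
I	ATC	0.55
I	ATT	0.40
I	ATA	0.05
L	CTG	0.55
L	TTA	0.12
L	TTG	0.12
L	CTC	0.10
L	CTT	0.08
L	CTA	0.03
K	AAA	0.70
K	AAG	0.30
M	ATG	1.00
F	TTC	0.55
F	TTT	0.45
P	CCG	0.50
P	CCA	0.20
P	CCT	0.18
P	CCC	0.12
S	TCT	0.30
S	AGC	0.25
S	TCC	0.20
S	AGT	0.10
S	TCA	0.10
S	TCG	0.05
T	ACC	0.40
T	ACT	0.30
T	ACA	0.17
T	ACG	0.13
W	TGG	1.00
Y	TAC	0.55
Y	TAT	0.45
V	GTT	0.35
V	GTG	0.30
V	GTA	0.20
V	GTC	0.15
*	TAA	0.60
*	TGA	0.25
*	TAG	0.15
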