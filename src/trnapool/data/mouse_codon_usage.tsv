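# Mus musculus codon usage, frequencies per 1000 codons, genome-wide CDS
# averages as tabulated in the Kazusa codon usage database (Mus musculus).
# Stop codons carry no amino-acid assignment and are marked "*".
codon	amino_acid	per_1000
TTT	Phe	17.2
TTC	Phe	21.8
TTA	Leu	6.7
TTG	Leu	13.4
CTT	Leu	13.4
CTC	Leu	20.2
CTA	Leu	8.1
CTG	Leu	39.5
ATT	Ile	15.4
ATC	Ile	22.5
ATA	Ile	7.4
ATG	Met	22.8
GTT	Val	10.7
GTC	Val	15.4
GTA	Val	7.4
GTG	Val	28.4
TCT	Ser	16.2
TCC	Ser	18.1
TCA	Ser	11.8
TCG	Ser	4.2
CCT	Pro	18.4
CCC	Pro	18.2
CCA	Pro	17.3
CCG	Pro	6.2
ACT	Thr	13.7
ACC	Thr	19.0
ACA	Thr	16.0
ACG	Thr	5.6
GCT	Ala	20.0
GCC	Ala	26.0
GCA	Ala	15.8
GCG	Ala	6.4
TAT	Tyr	12.2
TAC	Tyr	16.1
TAA	*	1.0
TAG	*	0.8
CAT	His	10.6
CAC	His	15.3
CAA	Gln	12.0
CAG	Gln	34.1
AAT	Asn	15.6
AAC	Asn	20.3
AAA	Lys	21.9
AAG	Lys	33.6
GAT	Asp	21.0
GAC	Asp	26.0
GAA	Glu	27.0
GAG	Glu	39.4
TGT	Cys	11.4
TGC	Cys	12.3
TGA	*	1.6
TGG	Trp	12.5
CGT	Arg	4.7
CGC	Arg	9.4
CGA	Arg	6.6
CGG	Arg	10.2
AGT	Ser	12.7
AGC	Ser	19.7
AGA	Arg	12.1
AGG	Arg	12.2
GGT	Gly	11.4
GGC	Gly	21.2
GGA	Gly	16.8
GGG	Gly	15.2
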