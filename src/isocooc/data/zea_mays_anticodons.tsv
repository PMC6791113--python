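amino_acid	anticodon	gene_count
Ala	AGC	1
Ala	CGC	1
Ala	GGC	1
Ala	UGC	1
Arg	ACG	1
Arg	CCG	1
Arg	CCU	1
Arg	GCG	1
Arg	UCG	1
Arg	UCU	1
Asn	GUU	1
Asp	GUC	1
Cys	GCA	1
Gln	CUG	1
Gln	UUG	1
Glu	CUC	1
Glu	UUC	1
Gly	CCC	1
Gly	GCC	1
Gly	UCC	1
His	GUG	1
Ile	AAU	1
Ile	GAU	1
Leu	AAG	1
Leu	CAA	1
Leu	CAG	1
Leu	GAG	1
Leu	UAA	1
Leu	UAG	1
Lys	CUU	1
Lys	UUU	1
Met	CAU	1
Phe	GAA	1
Pro	AGG	1
Pro	CGG	1
Pro	GGG	1
Pro	UGG	1
Ser	AGA	1
Ser	CGA	1
Ser	GCU	1
Ser	GGA	1
Ser	UGA	1
Thr	AGU	1
Thr	CGU	1
Thr	GGU	1
Thr	UGU	1
Trp	CCA	1
Tyr	GUA	1
Val	AAC	1
Val	CAC	1
Val	GAC	1
Val	UAC	1
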