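Name	Guides	Sequence	Tm	PctGC	Start	End	Chr
Chr9_35542587_F	crRNA_RF_1,crRNA_RF_2	AACAAGATGATGACGACGTG	56.2	45	35542587	35542606	Chr09
Chr9_35542966_R	crRNA_RF_1,crRNA_RF_2	GATGCACGAACTGATACTGT	55.6	45	35542947	35542966	Chr09
Chr9_35550584_F	crRNA_RF_3	CCCTGTATGCGAAAGACAAT	55.8	45	35550584	35550603	Chr09
Chr9_35550962_R	crRNA_RF_3	AAAAGACCACATGCATGCTG	57.3	45	35550943	35550962	Chr09
Chr9_35551563_F	crRNA_RF_4	TGATTGAATGTCTCCACCA	53.6	42.1	35551563	35551581	Chr09
Chr9_35552158_R	crRNA_RF_4	CACATGTGAGAGAGATTTGC	54.4	45	35552158	35552177	Chr09
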