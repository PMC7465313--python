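Name	Sequence	Chr	Start	End	Strand
crRNA_RF_1_F	GTCATATCTAAGGACCCGCGTGG	Chr09	35542701	35542723	+
crRNA_RF_2_F	TCTGTACTCCGTCTGTCGGTCGG	Chr09	35542848	35542870	+
crRNA_RF_3_R	AGAAGACTGTCAATCCCGAGTGG	Chr09	35550689	35550711	-
crRNA_RF_4_F	TGTCTGGAAAGTTTCTAACGCGG	Chr09	35551878	35551900	+
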