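context_id	scc_text	readthrough_pct	readthrough_sd
ZNF-574	GATCAGTGGC TGA CTCTGCCCGA	0.31	0.020
LDHB	AAAAGACCTG TGA CTAGTGAGCT	1.55	0.087
PPP1R3F	ATTCTCCCAA TAA AGCTTTACAG	0.18	0.009
LDHB[TGAT]	AAAAGACCTG TGA TTAGTGAGCT	0.17	0.009
LDHB[TAA]	AAAAGACCTG TAA CTAGTGAGCT	0.20	0.009
LDHB[TAAT]	AAAAGACCTG TAA TTAGTGAGCT	0.17	0.009
LENG1	CCTTACTCAC TGA CTCCTGAGGG	0.26	0.009
VASN	GCCCTACATC TAA GCCAGAGAGA	0.12	0.004
MDH1	TTCCTCTGCC TGA CTAGACAATG	2.91	0.147
PRDM10	CACCAAACCA TGA CTTCCACCCT	0.13	0.005
FBXL20	CATCATCCTA TGA CAATGGAGGT	0.10	0.006
THG1L	AGCCAGGCTT TGA CGGAAGAGTC	0.15	0.006
EDEM3	GGATGAGCTA TGA CTTGCTAAAC	0.66	0.027
EDN1	AGCACATTGG TGA CAGACCTTCG	0.25	0.008
UBQLN1	CCAGCCATCA TAG CAGCATTTCT	0.13	0.009
IRAK3	CAAAAAAGAA TAA ATTCTACCAG	0.10	0.007
SLC3A1	TACCTCGTGT TAG GCACCTTTAT	0.18	0.008
LEPRE1	GGATGAGCTA TGA CAGCGTCCAG	0.27	0.010
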