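position	A	C	G	T
-6	0.2892	0.2530	0.2651	0.1928
-5	0.3253	0.2651	0.1446	0.2651
-4	0.1566	0.2289	0.3494	0.2651
-3	0.2410	0.3373	0.2410	0.1807
-2	0.2651	0.1807	0.2048	0.3494
-1	0.2410	0.2530	0.2651	0.2410
4	0.2289	0.3133	0.3373	0.1205
5	0.2651	0.2530	0.1446	0.3373
6	0.2771	0.2169	0.2530	0.2530
7	0.2530	0.3133	0.2892	0.1446
8	0.3253	0.1687	0.2410	0.2651
9	0.1807	0.2771	0.2771	0.2651
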