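model	position	base	weight
LINiter	-6	A	-0.00041
LINiter	-6	C	-0.00105
LINiter	-6	G	0.00060
LINiter	-6	T	0.00200
LINiter	-5	A	0.00130
LINiter	-5	C	0.00164
LINiter	-5	G	-0.00077
LINiter	-5	T	-0.00103
LINiter	-4	A	-0.00028
LINiter	-4	C	0.00075
LINiter	-4	G	-0.00041
LINiter	-4	T	0.00108
LINiter	-3	A	-0.00073
LINiter	-3	C	-0.00004
LINiter	-3	G	0.00193
LINiter	-3	T	-0.00002
LINiter	-2	A	-0.00071
LINiter	-2	C	0.00133
LINiter	-2	G	-0.00048
LINiter	-2	T	0.00100
LINiter	-1	A	0.00016
LINiter	-1	C	0.00109
LINiter	-1	G	0.00043
LINiter	-1	T	-0.00054
LINiter	4	A	-0.00037
LINiter	4	C	0.00375
LINiter	4	G	-0.00156
LINiter	4	T	-0.00067
LINiter	5	A	-0.00068
LINiter	5	C	-0.00097
LINiter	5	G	-0.00008
LINiter	5	T	0.00287
LINiter	6	A	0.00276
LINiter	6	C	-0.00026
LINiter	6	G	-0.00059
LINiter	6	T	-0.00076
LINiter	7	A	-0.00020
LINiter	7	C	-0.00062
LINiter	7	G	0.00245
LINiter	7	T	-0.00049
LINiter	8	A	0.00105
LINiter	8	C	-0.00017
LINiter	8	G	-0.00058
LINiter	8	T	0.00084
LINiter	9	A	-0.00081
LINiter	9	C	0.00148
LINiter	9	G	0.00014
LINiter	9	T	0.00032
LINiter	stop	TAA	-0.00026
LINiter	stop	TAG	-0.00103
LINiter	stop	TGA	0.00243
LINfs3	4	A	0.00006
LINfs3	4	C	0.00351
LINfs3	4	G	-0.00111
LINfs3	4	T	-0.00064
LINfs3	5	A	-0.00071
LINfs3	5	C	-0.00056
LINfs3	5	G	0.00010
LINfs3	5	T	0.00299
LINfs3	6	A	0.00306
LINfs3	6	C	0.00021
LINfs3	6	G	-0.00093
LINfs3	6	T	-0.00053
LINfs3	stop	TAA	0.00005
LINfs3	stop	TAG	-0.00052
LINfs3	stop	TGA	0.00229
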