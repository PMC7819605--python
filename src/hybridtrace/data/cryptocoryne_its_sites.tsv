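id	group	count	43	44	141	142	186	194	230	250	422	451	479	607	623	642	660	667	668	688
GRIFFITHII	griffithii	1	C	T	A	A	G	A	G	A	T	C	T	C	A	A	C	-	-	T
CORDATA	cordata	1	T	-	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
H1	hybrid_clone	14	C	T	A	A	G	A	G	A	T	C	T	C	A	A	C	-	-	T
H2	hybrid_clone	6	T	-	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
H3	hybrid_clone	15	C	T	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
H4	hybrid_clone	4	C	T	G	A	G	A	T	G	C	T	C	C	A	G	C	-	-	C
H5	hybrid_clone	1	C	T	A	A	G	A	G	A	T	T	T	C	A	G	C	-	-	T
H6	hybrid_clone	1	C	T	G	A	G	A	T	G	C	T	C	C	A	G	C	-	C	C
H7	hybrid_clone	1	T	-	G	A	G	A	T	G	C	T	C	C	A	G	C	-	-	C
MIX_H1	mixture_control	1	C	T	A	A	G	A	G	A	T	C	T	C	A	A	C	-	-	T
MIX_H2	mixture_control	1	T	-	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
MIX_H3	mixture_control	4	C	T	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
SCHULZEI	schulzei	1	T	-	G	A	G	A	T	G	C	T	C	C	A	G	C	G	C	C
NURII	nurii	1	C	T	A	G	C	G	G	A	T	C	T	A	G	A	G	-	-	T
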