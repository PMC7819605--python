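id	group	count	148	164	165	166	167	168	169	241	263	367	410	494	543	550	1050	1089	1176	1182	1239	1389
PI	hybrid	1	G	-	-	-	-	-	-	T	T	G	T	T	T	T	G	A	T	T	C	T
KJ	hybrid	1	G	-	-	-	-	-	-	T	T	G	T	T	T	T	G	A	T	T	C	T
PK	hybrid	1	G	-	-	-	-	-	-	T	T	G	T	T	T	T	G	A	T	T	C	T
ST	cordata	1	G	-	-	-	-	-	-	T	T	G	T	T	T	T	G	A	T	T	C	T
BS	cordata	1	G	-	-	-	-	-	-	T	T	G	T	T	T	T	G	A	T	T	C	T
MU	cordata	1	G	-	-	-	-	-	-	T	T	G	T	T	G	T	G	A	T	T	C	T
GA	cordata	1	G	-	-	-	-	-	-	T	T	T	T	T	G	T	G	A	T	T	C	A
PAN	cordata	1	G	-	-	-	-	-	-	T	T	G	C	T	G	T	A	A	G	T	C	T
SL	hybrid	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
SED	hybrid	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
GF	griffithii	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
KUL	griffithii	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
BOT	griffithii	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
SIN	griffithii	1	G	C	T	G	T	A	T	T	G	G	C	T	G	G	A	G	G	C	A	T
MT	hybrid	1	A	C	T	G	T	A	T	T	G	G	C	T	G	T	A	G	G	C	A	T
SU	hybrid	1	A	C	T	G	T	A	T	T	G	G	C	T	G	T	A	G	G	C	A	T
BIN	griffithii	1	A	C	T	G	T	A	T	T	G	G	C	T	G	T	A	G	G	C	A	T
SPAN	schulzei	1	G	-	-	-	-	-	-	G	T	T	T	A	G	T	G	A	T	T	C	A
SKJ	schulzei	1	G	-	-	-	-	-	-	G	T	T	T	A	G	T	G	A	T	T	C	A
NKJ	nurii	1	G	-	-	-	-	-	-	G	T	T	T	A	G	T	G	A	T	T	C	A
NSK	nurii	1	G	-	-	-	-	-	-	G	T	T	T	A	G	T	G	A	T	T	C	A
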