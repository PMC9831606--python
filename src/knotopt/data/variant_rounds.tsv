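name	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24	25	26	27	28	29	30
WT PTx2	Y	C	Q	K	W	M	W	T	C	D	S	E	R	K	C	C	E	G	M	V	C	R	L	W	C	K	K	K	L	W
PTx2-2955	Y	C	Q	K	A	F	W	T	C	D	S	E	R	K	C	C	E	G	L	R	C	X	L	W	C	R	K	E	L	W
PTx2-3066	Y	C	Q	K	W	M	Q	T	C	D	K	D	R	K	C	C	E	G	L	R	C	R	L	W	C	R	K	E	L	L
PTx2-3127	Q	C	Q	K	W	M	Q	T	C	D	K	D	R	K	C	C	E	G	F	R	C	R	L	W	C	R	K	E	L	L
PTx2-3258	H	C	Q	K	W	M	Q	T	C	D	K	D	R	K	C	C	E	G	F	R	C	R	L	W	C	R	K	E	L	L
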