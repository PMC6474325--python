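# threshold: 45.0
# template: VTYNTLISGLCKAGRLEEALELFREMKERGIEPDV
# Hand-built approximation of a canonical 35-residue P-class repeat
# consensus; +3 primary, +1 chemically similar alternates, -1 otherwise.
# Positions 1 and 6 are uninformative (they carry specificity letters).
pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
2	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	3	-1	-1	-1
3	-1	-1	-1	-1	1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	3
4	-1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1	3	-1	-1	-1	1	-1	-1	-1	-1
5	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	3	-1	-1	-1
6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
7	-1	-1	-1	-1	-1	-1	-1	3	-1	1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1
8	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	3	1	-1	-1	-1
9	1	-1	-1	-1	-1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
10	-1	-1	-1	-1	-1	-1	-1	1	-1	3	1	-1	-1	-1	-1	-1	-1	-1	-1	-1
11	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
12	-1	-1	-1	-1	-1	-1	-1	-1	3	-1	-1	-1	-1	1	1	-1	-1	-1	-1	-1
13	3	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
14	1	-1	-1	-1	-1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
15	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	1	3	-1	-1	-1	-1	-1
16	-1	-1	-1	-1	-1	-1	-1	1	-1	3	1	-1	-1	-1	-1	-1	-1	-1	-1	-1
17	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
18	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
19	3	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
20	-1	-1	-1	-1	-1	-1	-1	1	-1	3	1	-1	-1	-1	-1	-1	-1	-1	-1	-1
21	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
22	-1	-1	-1	-1	-1	-1	-1	1	-1	3	1	-1	-1	-1	-1	-1	-1	-1	-1	-1
23	-1	-1	-1	-1	3	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1
24	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	1	3	-1	-1	-1	-1	-1
25	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
26	-1	-1	-1	-1	-1	-1	-1	1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1
27	-1	-1	-1	-1	-1	-1	-1	-1	3	-1	-1	-1	-1	1	1	-1	-1	-1	-1	-1
28	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
29	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	1	3	-1	-1	-1	-1	-1
30	1	-1	-1	-1	-1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1
31	-1	-1	-1	-1	-1	-1	-1	3	-1	1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1
32	-1	-1	1	3	-1	-1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1
33	1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	3	-1	-1	1	-1	-1	-1	-1
34	-1	-1	3	1	-1	-1	-1	-1	-1	-1	-1	1	-1	-1	-1	-1	-1	-1	-1	-1
35	-1	-1	-1	-1	-1	-1	-1	1	-1	1	-1	-1	-1	-1	-1	-1	-1	3	-1	-1
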