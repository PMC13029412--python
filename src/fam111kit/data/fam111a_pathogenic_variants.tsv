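index	token	regions	diseases
1	F231A	PIP	Decreased DNA binding
2	C226F *	UBL2/DBD|Mutation Block 1|Motif 1	Disrupted protein function
3	R230S *	UBL2/DBD|Mutation Block 1|Motif 1	Disrupted protein function
4	E285Q *	UBL2/DBD|Mutation Block 1	OCS
5	L292fs *	UBL2/DBD|Mutation Block 1	KCS2
6	I311F	Mutation Block 1	KCS2|OCS
7	G323E	Mutation Block 1	KCS2
8	L326I	Mutation Block 1	KCS2
9	T338A	Mutation Block 1	KCS2|OCS
10	S342del	Mutation Block 1	KCS2|OCS
11	V357[I/fs] *	Mutation Block 1|Motif 2	Disrupted protein function
12	I380V *	SPD|Mutation Block 2|Motif 3	OCS
13	T382I *	SPD|Mutation Block 2|Motif 3	Disrupted protein function
14	R384W *	SPD|Mutation Block 2|Motif 3	Disrupted protein function
15	H385Y *	SPD|Mutation Block 2|Motif 3	KCS2
16	D439	SPD|Mutation Block 2|Motif 4	KCS2
17	H470Y	SPD|Mutation Block 2|Motif 5	KCS2
18	C485F	SPD|Mutation Block 2	KCS2
19	Y511H	SPD|Mutation Block 2	KCS2
20	M514I	SPD|Mutation Block 2	KCS2|OCS
21	F520C	SPD|Mutation Block 2	KCS2
22	P527T	SPD|Mutation Block 2	KCS2|OCS
23	D528G	SPD|Mutation Block 2	KCS2|OCS
24	E535G	SPD|Mutation Block 2	KCS2
25	S541[Y/P]	SPD|Mutation Block 2|Motif 6	KCS2
26	G542 [S/V/D] *	SPD|Mutation Block 2|Motif 6	Disrupted protein function FAM111A-related disorders
27	D547Y *	SPD|Mutation Block 2|Motif 6	Disrupted protein function
28	L552F *	SPD|Mutation Block 2|Motif 7	Disrupted protein function
29	M555T *	SPD|Mutation Block 2|Motif 7	Disrupted protein function
30	G559D *	SPD|Mutation Block 2|Motif 7	Disrupted protein function
31	Y562S	Mutation Block 2	KCS2|OCS
32	R569H	Mutation Block 2	KCS2
33	I572del	Mutation Block 2	KCS2
34	K586K	Mutation Block 2	KCS2
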