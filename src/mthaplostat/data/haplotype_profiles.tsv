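haplotype	242	369	393	462	513	531	571	596	631	684	695	732	798	812	840	841	928	929	961	1039	1082	1140	1220	1247	1328	1387	1610	1629	1632	1646	1801
H1	C	C	A	T	C	G	G	A	T	T	G	C	T	G	T	A	A	A	A	C	C	A	A	T	A	T	C	C	T	C	A
H2	.	.	.	.	.	A	.	.	.	.	.	.	.	.	C	.	.	-	.	.	.	.	.	C	.	.	.	T	.	.	.
H3	.	.	.	.	T	A	.	.	.	.	.	.	.	.	.	.	.	-	G	.	.	.	G	.	.	.	.	T	.	.	.
H4	.	.	.	C	.	A	.	.	.	.	A	T	C	.	.	.	-	-	G	.	T	.	.	.	.	.	T	T	.	T	.
H5	.	T	.	.	.	A	.	.	C	.	.	.	.	.	.	.	-	-	G	.	.	.	.	.	.	.	.	T	.	T	.
H6	.	T	.	.	.	A	.	.	C	.	.	.	.	A	.	.	-	-	G	.	.	.	.	.	.	.	.	T	.	T	.
H7	T	T	.	.	.	A	.	.	C	.	.	.	.	.	.	.	-	-	G	.	.	G	.	.	.	.	.	T	.	T	.
H8	T	T	.	.	.	A	.	.	.	C	.	.	.	.	.	.	-	-	G	.	.	G	.	.	.	.	.	T	.	T	.
H9	.	.	.	.	.	A	.	.	.	C	.	.	.	.	.	G	-	-	G	.	.	.	.	.	G	.	.	T	.	T	.
H10	.	.	.	.	.	A	.	.	.	C	.	.	.	.	.	.	-	-	G	.	.	.	.	.	G	C	.	T	.	T	.
H11	.	.	.	.	.	A	.	.	.	C	.	.	.	.	.	.	-	-	G	T	.	.	.	.	G	C	.	T	.	T	.
H12	.	.	.	.	.	A	A	.	.	C	.	.	.	.	.	.	-	-	G	T	.	.	.	.	G	C	.	T	.	T	.
Z1	.	.	.	.	.	A	.	.	.	C	.	.	.	.	.	.	-	-	G	.	.	.	.	.	G	C	.	T	C	T	.
Z2	.	.	.	.	.	A	.	.	.	C	.	.	.	.	.	.	-	-	G	.	.	.	.	.	G	C	.	T	C	T	T
Z3	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
Z4	.	.	G	.	.	A	.	.	.	C	.	.	.	.	.	G	-	-	G	.	.	.	.	.	G	.	.	T	.	T	.
Z5	.	.	.	.	.	A	.	G	.	C	.	.	.	.	.	G	-	-	G	.	.	.	.	.	G	.	.	T	.	T	.
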