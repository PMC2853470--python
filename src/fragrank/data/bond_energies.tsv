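# Standard bond dissociation enthalpies (homolytic), kJ/mol.
# Literature average values per element pair and bond order.
# columns: element_1  element_2  bond_order  enthalpy_kj_mol
C	C	1	348
C	C	2	614
C	C	3	839
C	N	1	293
C	N	2	615
C	N	3	891
C	O	1	358
C	O	2	799
C	S	1	259
C	S	2	573
C	P	1	264
C	F	1	485
C	Cl	1	328
C	Br	1	276
C	I	1	240
N	N	1	163
N	N	2	418
N	N	3	941
N	O	1	201
N	O	2	607
N	P	1	209
O	O	1	146
O	O	2	495
O	P	1	335
O	P	2	544
O	S	1	265
O	S	2	522
S	S	1	266
P	P	1	201
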