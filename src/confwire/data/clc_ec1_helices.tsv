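# Residue ranges of the transmembrane helices (A..R) in CLC-ec1 numbering.
# Curated defaults for annotation of distance-matrix exports; edit to taste.
# helix	first_resid	last_resid
A	12	30
B	32	58
C	62	90
D	95	114
E	122	142
F	148	166
G	172	192
H	196	212
I	214	232
J	235	252
K	258	280
L	284	312
M	318	340
N	346	368
O	372	385
P	389	408
Q	414	430
R	434	450
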