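# Inverted-topology repeat correspondence for CLC-ec1 (Repeat 1: helices B-I,
# Repeat 2: helices J-Q). Each row pairs an equal-length core segment of a
# Repeat-1 helix with its structural counterpart in Repeat 2. This pairing is
# a curated, user-editable default: repeat-RMSD values depend on it.
# helix_pair	r1_first	r1_last	r2_first	r2_last
B-J	35	47	240	252
C-K	65	80	260	275
D-L	98	112	290	304
E-M	125	140	320	335
F-N	153	164	350	361
G-O	176	188	373	385
H-P	198	210	392	404
I-Q	215	223	416	424
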