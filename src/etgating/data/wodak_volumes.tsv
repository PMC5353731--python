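# Mean residue volumes (side chain inclusive), Angstrom^3.
# Pontius, Richelle & Wodak (1996) J Mol Biol 264:121-136, Table of
# average residue volumes computed from high-resolution crystal structures.
A	91.5
R	196.1
N	138.3
D	135.2
C	114.4
Q	156.4
E	154.6
G	67.5
H	163.2
I	162.6
L	163.4
K	162.5
M	165.9
F	198.8
P	123.4
S	102.0
T	126.0
W	237.2
Y	209.8
V	138.4
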