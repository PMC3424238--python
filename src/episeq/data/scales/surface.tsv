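# Surface-exposure propensity: interior-to-surface transfer free energy
# (Janin, Nature 277:491-492, 1979). Higher = more buried.
# residue	value
A	0.3
C	0.9
D	-0.6
E	-0.7
F	0.5
G	0.3
H	-0.1
I	0.7
K	-1.8
L	0.5
M	0.4
N	-0.5
P	-0.3
Q	-0.7
R	-1.4
S	-0.1
T	-0.2
V	0.6
W	0.3
Y	-0.4
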