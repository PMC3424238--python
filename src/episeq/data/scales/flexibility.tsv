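# Chain flexibility: normalized average B-factors of backbone atoms
# (Karplus & Schulz, Naturwissenschaften 72:212-213, 1985).
# residue	value
A	0.984
C	0.906
D	1.068
E	1.094
F	0.915
G	1.031
H	0.950
I	0.927
K	1.102
L	0.935
M	0.952
N	1.048
P	1.049
Q	1.037
R	1.008
S	1.046
T	0.997
V	0.931
W	0.904
Y	0.929
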