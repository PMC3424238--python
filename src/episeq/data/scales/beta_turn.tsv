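# Beta-turn propensity: Chou-Fasman turn conformational parameters as
# used in turn-based epitope scales (Pellequer, Westhof & Van Regenmortel,
# Immunol Lett 36:83-99, 1993).
# residue	value
A	0.66
C	1.19
D	1.46
E	0.74
F	0.60
G	1.56
H	0.95
I	0.47
K	1.01
L	0.59
M	0.60
N	1.56
P	1.52
Q	0.98
R	0.95
S	1.43
T	0.96
V	0.50
W	0.96
Y	1.14
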