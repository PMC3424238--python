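# Surface accessibility (surface probability) scale
# (Emini et al., J Virol 55:836-839, 1985).
# residue	value
A	0.815
C	0.394
D	1.283
E	1.445
F	0.695
G	0.714
H	1.180
I	0.603
K	1.545
L	0.603
M	0.714
N	1.296
P	1.236
Q	1.348
R	1.475
S	1.115
T	1.184
V	0.606
W	0.808
Y	1.089
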