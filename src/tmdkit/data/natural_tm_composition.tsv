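# Amino-acid composition of natural single-span TM helices
# (approximate frequencies; strongly hydrophobic-biased).
aa	frequency
A	0.090
C	0.025
D	0.010
E	0.010
F	0.095
G	0.070
H	0.015
I	0.115
K	0.015
L	0.170
M	0.045
N	0.015
P	0.020
Q	0.015
R	0.015
S	0.055
T	0.050
V	0.110
W	0.030
Y	0.030
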