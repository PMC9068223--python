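# Default depth-dependent lipophilicity profile (kcal/mol).
# Per-residue apparent insertion free energy from the biological
# (translocon) hydrophobicity scale, weighted by a symmetric taper
# that is 1 in the slab core (|z| <= 9 A) and 0 outside |z| = 22.5 A.
aa	z	energy
A	-22.5	0.0000
A	-15	0.0550
A	-9	0.1100
A	0	0.1100
A	9	0.1100
A	15	0.0550
A	22.5	0.0000
C	-22.5	-0.0000
C	-15	-0.0650
C	-9	-0.1300
C	0	-0.1300
C	9	-0.1300
C	15	-0.0650
C	22.5	-0.0000
D	-22.5	0.0000
D	-15	1.7450
D	-9	3.4900
D	0	3.4900
D	9	3.4900
D	15	1.7450
D	22.5	0.0000
E	-22.5	0.0000
E	-15	1.3400
E	-9	2.6800
E	0	2.6800
E	9	2.6800
E	15	1.3400
E	22.5	0.0000
F	-22.5	-0.0000
F	-15	-0.1600
F	-9	-0.3200
F	0	-0.3200
F	9	-0.3200
F	15	-0.1600
F	22.5	-0.0000
G	-22.5	0.0000
G	-15	0.3700
G	-9	0.7400
G	0	0.7400
G	9	0.7400
G	15	0.3700
G	22.5	0.0000
H	-22.5	0.0000
H	-15	1.0300
H	-9	2.0600
H	0	2.0600
H	9	2.0600
H	15	1.0300
H	22.5	0.0000
I	-22.5	-0.0000
I	-15	-0.3000
I	-9	-0.6000
I	0	-0.6000
I	9	-0.6000
I	15	-0.3000
I	22.5	-0.0000
K	-22.5	0.0000
K	-15	1.3550
K	-9	2.7100
K	0	2.7100
K	9	2.7100
K	15	1.3550
K	22.5	0.0000
L	-22.5	-0.0000
L	-15	-0.2750
L	-9	-0.5500
L	0	-0.5500
L	9	-0.5500
L	15	-0.2750
L	22.5	-0.0000
M	-22.5	-0.0000
M	-15	-0.0500
M	-9	-0.1000
M	0	-0.1000
M	9	-0.1000
M	15	-0.0500
M	22.5	-0.0000
N	-22.5	0.0000
N	-15	1.0250
N	-9	2.0500
N	0	2.0500
N	9	2.0500
N	15	1.0250
N	22.5	0.0000
P	-22.5	0.0000
P	-15	1.1150
P	-9	2.2300
P	0	2.2300
P	9	2.2300
P	15	1.1150
P	22.5	0.0000
Q	-22.5	0.0000
Q	-15	1.1800
Q	-9	2.3600
Q	0	2.3600
Q	9	2.3600
Q	15	1.1800
Q	22.5	0.0000
R	-22.5	0.0000
R	-15	1.2900
R	-9	2.5800
R	0	2.5800
R	9	2.5800
R	15	1.2900
R	22.5	0.0000
S	-22.5	0.0000
S	-15	0.4200
S	-9	0.8400
S	0	0.8400
S	9	0.8400
S	15	0.4200
S	22.5	0.0000
T	-22.5	0.0000
T	-15	0.2600
T	-9	0.5200
T	0	0.5200
T	9	0.5200
T	15	0.2600
T	22.5	0.0000
V	-22.5	-0.0000
V	-15	-0.1550
V	-9	-0.3100
V	0	-0.3100
V	9	-0.3100
V	15	-0.1550
V	22.5	-0.0000
W	-22.5	0.0000
W	-15	0.1500
W	-9	0.3000
W	0	0.3000
W	9	0.3000
W	15	0.1500
W	22.5	0.0000
Y	-22.5	0.0000
Y	-15	0.3400
Y	-9	0.6800
Y	0	0.6800
Y	9	0.6800
Y	15	0.3400
Y	22.5	0.0000
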