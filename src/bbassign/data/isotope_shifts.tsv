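residue	nucleus	delta
A	CA	-0.600
A	CB	-1.000
A	CO	-0.140
C	CA	-0.500
C	CB	-0.700
C	CO	-0.110
D	CA	-0.500
D	CB	-0.700
D	CO	-0.110
E	CA	-0.560
E	CB	-0.900
E	CO	-0.110
F	CA	-0.500
F	CB	-0.700
F	CO	-0.110
G	CA	-0.600
G	CO	-0.100
H	CA	-0.500
H	CB	-0.700
H	CO	-0.110
I	CA	-0.550
I	CB	-0.900
I	CO	-0.080
K	CA	-0.560
K	CB	-0.900
K	CO	-0.110
L	CA	-0.530
L	CB	-0.800
L	CO	-0.110
M	CA	-0.560
M	CB	-0.900
M	CO	-0.110
N	CA	-0.500
N	CB	-0.700
N	CO	-0.110
P	CA	-0.560
P	CB	-0.900
P	CO	-0.110
Q	CA	-0.560
Q	CB	-0.900
Q	CO	-0.110
R	CA	-0.560
R	CB	-0.900
R	CO	-0.110
S	CA	-0.500
S	CB	-0.700
S	CO	-0.110
T	CA	-0.490
T	CB	-0.700
T	CO	-0.080
V	CA	-0.580
V	CB	-1.000
V	CO	-0.080
W	CA	-0.500
W	CB	-0.700
W	CO	-0.110
Y	CA	-0.500
Y	CB	-0.700
Y	CO	-0.110
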