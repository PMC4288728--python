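residue	nucleus	rc	helix_delta	strand_delta
A	CA	52.50	2.60	-1.40
A	CB	19.10	-0.40	2.20
A	CO	177.80	1.80	-1.60
C	CA	58.20	2.60	-1.40
C	CB	28.00	-0.40	2.20
C	CO	174.60	1.80	-1.60
D	CA	54.20	2.60	-1.40
D	CB	41.10	-0.40	2.20
D	CO	176.30	1.80	-1.60
E	CA	56.60	2.60	-1.40
E	CB	29.90	-0.40	2.20
E	CO	176.60	1.80	-1.60
F	CA	57.70	2.60	-1.40
F	CB	39.60	-0.40	2.20
F	CO	175.80	1.80	-1.60
G	CA	45.10	2.60	-1.40
G	CO	174.90	1.80	-1.60
H	CA	55.00	2.60	-1.40
H	CB	29.00	-0.40	2.20
H	CO	174.10	1.80	-1.60
I	CA	61.10	2.60	-1.40
I	CB	38.80	-0.40	2.20
I	CO	176.40	1.80	-1.60
K	CA	56.20	2.60	-1.40
K	CB	33.10	-0.40	2.20
K	CO	176.60	1.80	-1.60
L	CA	55.10	2.60	-1.40
L	CB	42.40	-0.40	2.20
L	CO	177.60	1.80	-1.60
M	CA	55.40	2.60	-1.40
M	CB	32.90	-0.40	2.20
M	CO	176.30	1.80	-1.60
N	CA	53.10	2.60	-1.40
N	CB	38.90	-0.40	2.20
N	CO	175.20	1.80	-1.60
P	CA	63.30	2.60	-1.40
P	CB	31.70	-0.40	2.20
P	CO	177.30	1.80	-1.60
Q	CA	55.70	2.60	-1.40
Q	CB	29.40	-0.40	2.20
Q	CO	176.00	1.80	-1.60
R	CA	56.00	2.60	-1.40
R	CB	30.90	-0.40	2.20
R	CO	176.30	1.80	-1.60
S	CA	58.30	2.60	-1.40
S	CB	63.80	-0.40	2.20
S	CO	174.60	1.80	-1.60
T	CA	61.80	2.60	-1.40
T	CB	69.80	-0.40	2.20
T	CO	174.70	1.80	-1.60
V	CA	62.20	2.60	-1.40
V	CB	32.90	-0.40	2.20
V	CO	176.30	1.80	-1.60
W	CA	57.50	2.60	-1.40
W	CB	29.60	-0.40	2.20
W	CO	176.10	1.80	-1.60
Y	CA	57.90	2.60	-1.40
Y	CB	38.80	-0.40	2.20
Y	CO	175.90	1.80	-1.60
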