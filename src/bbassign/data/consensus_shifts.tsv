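residue	ss	nucleus	mean	sd
A	helix	CA	55.10	0.80
A	helix	CB	18.70	1.00
A	helix	CO	179.60	0.90
A	strand	CA	51.10	1.00
A	strand	CB	21.30	1.20
A	strand	CO	176.20	1.10
A	coil	CA	52.50	1.00
A	coil	CB	19.10	1.10
A	coil	CO	177.80	1.00
C	helix	CA	60.80	0.80
C	helix	CB	27.60	1.00
C	helix	CO	176.40	0.90
C	strand	CA	56.80	1.00
C	strand	CB	30.20	1.20
C	strand	CO	173.00	1.10
C	coil	CA	58.20	1.00
C	coil	CB	28.00	1.10
C	coil	CO	174.60	1.00
D	helix	CA	56.80	0.80
D	helix	CB	40.70	1.00
D	helix	CO	178.10	0.90
D	strand	CA	52.80	1.00
D	strand	CB	43.30	1.20
D	strand	CO	174.70	1.10
D	coil	CA	54.20	1.00
D	coil	CB	41.10	1.10
D	coil	CO	176.30	1.00
E	helix	CA	59.20	0.80
E	helix	CB	29.50	1.00
E	helix	CO	178.40	0.90
E	strand	CA	55.20	1.00
E	strand	CB	32.10	1.20
E	strand	CO	175.00	1.10
E	coil	CA	56.60	1.00
E	coil	CB	29.90	1.10
E	coil	CO	176.60	1.00
F	helix	CA	60.30	0.80
F	helix	CB	39.20	1.00
F	helix	CO	177.60	0.90
F	strand	CA	56.30	1.00
F	strand	CB	41.80	1.20
F	strand	CO	174.20	1.10
F	coil	CA	57.70	1.00
F	coil	CB	39.60	1.10
F	coil	CO	175.80	1.00
G	helix	CA	47.70	0.80
G	helix	CO	176.70	0.90
G	strand	CA	43.70	1.00
G	strand	CO	173.30	1.10
G	coil	CA	45.10	1.00
G	coil	CO	174.90	1.00
H	helix	CA	57.60	0.80
H	helix	CB	28.60	1.00
H	helix	CO	175.90	0.90
H	strand	CA	53.60	1.00
H	strand	CB	31.20	1.20
H	strand	CO	172.50	1.10
H	coil	CA	55.00	1.00
H	coil	CB	29.00	1.10
H	coil	CO	174.10	1.00
I	helix	CA	63.70	0.80
I	helix	CB	38.40	1.00
I	helix	CO	178.20	0.90
I	strand	CA	59.70	1.00
I	strand	CB	41.00	1.20
I	strand	CO	174.80	1.10
I	coil	CA	61.10	1.00
I	coil	CB	38.80	1.10
I	coil	CO	176.40	1.00
K	helix	CA	58.80	0.80
K	helix	CB	32.70	1.00
K	helix	CO	178.40	0.90
K	strand	CA	54.80	1.00
K	strand	CB	35.30	1.20
K	strand	CO	175.00	1.10
K	coil	CA	56.20	1.00
K	coil	CB	33.10	1.10
K	coil	CO	176.60	1.00
L	helix	CA	57.70	0.80
L	helix	CB	42.00	1.00
L	helix	CO	179.40	0.90
L	strand	CA	53.70	1.00
L	strand	CB	44.60	1.20
L	strand	CO	176.00	1.10
L	coil	CA	55.10	1.00
L	coil	CB	42.40	1.10
L	coil	CO	177.60	1.00
M	helix	CA	58.00	0.80
M	helix	CB	32.50	1.00
M	helix	CO	178.10	0.90
M	strand	CA	54.00	1.00
M	strand	CB	35.10	1.20
M	strand	CO	174.70	1.10
M	coil	CA	55.40	1.00
M	coil	CB	32.90	1.10
M	coil	CO	176.30	1.00
N	helix	CA	55.70	0.80
N	helix	CB	38.50	1.00
N	helix	CO	177.00	0.90
N	strand	CA	51.70	1.00
N	strand	CB	41.10	1.20
N	strand	CO	173.60	1.10
N	coil	CA	53.10	1.00
N	coil	CB	38.90	1.10
N	coil	CO	175.20	1.00
P	helix	CA	65.90	0.80
P	helix	CB	31.30	1.00
P	helix	CO	179.10	0.90
P	strand	CA	61.90	1.00
P	strand	CB	33.90	1.20
P	strand	CO	175.70	1.10
P	coil	CA	63.30	1.00
P	coil	CB	31.70	1.10
P	coil	CO	177.30	1.00
Q	helix	CA	58.30	0.80
Q	helix	CB	29.00	1.00
Q	helix	CO	177.80	0.90
Q	strand	CA	54.30	1.00
Q	strand	CB	31.60	1.20
Q	strand	CO	174.40	1.10
Q	coil	CA	55.70	1.00
Q	coil	CB	29.40	1.10
Q	coil	CO	176.00	1.00
R	helix	CA	58.60	0.80
R	helix	CB	30.50	1.00
R	helix	CO	178.10	0.90
R	strand	CA	54.60	1.00
R	strand	CB	33.10	1.20
R	strand	CO	174.70	1.10
R	coil	CA	56.00	1.00
R	coil	CB	30.90	1.10
R	coil	CO	176.30	1.00
S	helix	CA	60.90	0.80
S	helix	CB	63.40	1.00
S	helix	CO	176.40	0.90
S	strand	CA	56.90	1.00
S	strand	CB	66.00	1.20
S	strand	CO	173.00	1.10
S	coil	CA	58.30	1.00
S	coil	CB	63.80	1.10
S	coil	CO	174.60	1.00
T	helix	CA	64.40	0.80
T	helix	CB	69.40	1.00
T	helix	CO	176.50	0.90
T	strand	CA	60.40	1.00
T	strand	CB	72.00	1.20
T	strand	CO	173.10	1.10
T	coil	CA	61.80	1.00
T	coil	CB	69.80	1.10
T	coil	CO	174.70	1.00
V	helix	CA	64.80	0.80
V	helix	CB	32.50	1.00
V	helix	CO	178.10	0.90
V	strand	CA	60.80	1.00
V	strand	CB	35.10	1.20
V	strand	CO	174.70	1.10
V	coil	CA	62.20	1.00
V	coil	CB	32.90	1.10
V	coil	CO	176.30	1.00
W	helix	CA	60.10	0.80
W	helix	CB	29.20	1.00
W	helix	CO	177.90	0.90
W	strand	CA	56.10	1.00
W	strand	CB	31.80	1.20
W	strand	CO	174.50	1.10
W	coil	CA	57.50	1.00
W	coil	CB	29.60	1.10
W	coil	CO	176.10	1.00
Y	helix	CA	60.50	0.80
Y	helix	CB	38.40	1.00
Y	helix	CO	177.70	0.90
Y	strand	CA	56.50	1.00
Y	strand	CB	41.00	1.20
Y	strand	CO	174.30	1.10
Y	coil	CA	57.90	1.00
Y	coil	CB	38.80	1.10
Y	coil	CO	175.90	1.00
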