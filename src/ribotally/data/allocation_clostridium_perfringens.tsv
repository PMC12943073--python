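amino_acid	n_aa	cfs	m_trna
A	49128	4	4
C	10316	2	2
D	50881	2	3
E	74540	2	4
F	42363	2	4
G	60495	4	12
H	11807	2	2
I	87449	3	4
K	85533	2	7
L	85534	6	9
N	59147	2	4
P	24866	4	3
Q	18015	2	3
R	30389	6	7
S	56898	6	5
T	42052	4	5
V	59549	4	4
W	6536	1	2
Y	36940	2	3
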