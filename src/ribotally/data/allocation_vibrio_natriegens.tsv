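amino_acid	n_aa	cfs	m_trna
A	126982	4	7
C	15568	2	4
D	80754	2	6
E	95956	2	6
F	60938	2	4
G	103326	4	11
H	32846	2	2
I	92838	3	5
K	76752	2	4
L	151573	6	17
N	61206	2	5
P	58807	4	3
Q	64988	2	6
R	65549	6	11
S	97945	6	7
T	79535	4	7
V	107453	4	6
W	18772	1	2
Y	44625	2	6
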