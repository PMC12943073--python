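species	kingdom	accessions	generation_time	gt_rank
Clostridium perfringens	Bacillati	NZ_CP065681	~7-15 min	1
Staphylococcus aureus	Bacillati	NC_007795	~21-35 min	2
Bacillus subtilis	Bacillati	NC_000964.3	~30-70 min	3
Streptococcus pneumoniae	Bacillati	NZ_LN831051	~30-60 min	3
Listeria monocytogenes	Bacillati	NC_003210	~45-60 min	3
Lactobacillus plantarum	Bacillati	NZ_CP028221	~50-70 min	3
Mycolicibacterium smegmatis	Bacillati	NZ_CP054795.1	~2 h	5
Mycobacterioides abscessus	Bacillati	NZ_CP034181.1	~4-5 h	5
Mycobacterium tuberculosis	Bacillati	NC_000962.3	~20-30 h	6
Mycobacterium leprae	Bacillati	NZ_CP029543.1	~7 days	7
Vibrio natriegens	Pseudomonadati	NZ_CP009977,NZ_CP009978.1	~10 min	1
Vibrio cholerae	Pseudomonadati	NZ_CP043554,NZ_CP043556.1	~16-20 min	2
Escherichia coli	Pseudomonadati	NC_000913.3	~20-30 min	2
Pseudomonas aeruginosa	Pseudomonadati	NC_002516	~25-30 min	2
Salmonella enterica	Pseudomonadati	NC_003197	~20-30 min	2
Haemophilus influenzae	Pseudomonadati	NZ_CP007470.1	~103-107 min	4
Chlamydia trachomatis	Pseudomonadati	NC_000117	~1.8-4.6 h	5
Helicobacter pylori	Pseudomonadati	NZ_AP026446	~2.5-3 h	5
Campylobacter jejuni	Pseudomonadati	NC_002163	~2-3 h	5
Borrelia burgdorferi	Pseudomonadati	NZ_ABCW02000001,NZ_ABCW02000002,NZ_ABCW02000003,NZ_ABCW02000004	~8.3-24 h	6
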