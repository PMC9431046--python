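asv_id	run	max_reads_samples	max_reads_blanks	removed
Staphylococcus_1	Run1	10	2	True
Prevotella_1	Run1	406	16	True
Fusobacterium_1	Run1	10	4	True
Fusobacterium_2	Run1	6	13	True
Caulobacter_1	Run1	6	9	True
Lactobacillus_1	Run2	79	74	False
Bifidobacterium	Run2	81	18	False
Lactobacillus_2	Run2	54	48	False
Snodgrasella	Run3	22554	3	False
Ralstonia	Run3	82	59	False
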