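feature	p_adjusted	fold_change
hsa-miR-29c-3p	0.0002	2.2
hsa-miR-193a-5p	0.0029	3.3
hsa-miR-378a-3p	0.0029	2.6
hsa-miR-1260a	0.0039	3.0
hsa-miR-34a-5p	0.0043	7.1
hsa-miR-194-5p	0.0064	2.5
hsa-miR-22-3p	0.0074	2.3
hsa-miR-99a-5p	0.0097	2.2
hsa-miR-885-5p	0.0110	5.8
hsa-miR-210-3p	0.0215	2.1
hsa-miR-629-5p	0.0226	2.6
hsa-miR-660-5p	0.0226	2.1
hsa-miR-1972	0.0226	4.1
hsa-miR-215-5p	0.0278	2.4
hsa-miR-374b-5p	0.0029	-2.6
hsa-miR-199a-5p	0.0104	-3.0
hsa-miR-199a-3p	0.0110	-2.3
hsa-miR-744-5p	0.0137	-2.3
hsa-miR-221-3p	0.0211	-2.1
hsa-miR-485-3p	0.0219	-3.5
hsa-miR-382-5p	0.0226	-2.5
hsa-miR-543	0.0233	-2.8
hsa-miR-409-3p	0.0255	-4.6
hsa-miR-339-5p	0.0255	-2.1
hsa-miR-127-3p	0.0278	-6.1
hsa-miR-28-5p	0.0376	-2.2
hsa-miR-375	0.0472	-2.4
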