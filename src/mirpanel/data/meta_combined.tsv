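biofluid	feature	combined_p	rank
plasma	hsa-miR-34a-5p	1.38598e-9	1
plasma	hsa-miR-192-5p	1.68099e-7	2
plasma	hsa-miR-193a-5p	2.07056e-6	3
plasma	hsa-miR-194-5p	5.05358e-6	4
plasma	hsa-miR-215-5p	1.64213e-5	5
plasma	hsa-miR-22-3p	0.000128536	6
plasma	hsa-miR-10b-5p	0.000169857	7
plasma	hsa-miR-363-3p	0.000235272	8
plasma	hsa-miR-107	0.000294182	9
plasma	hsa-miR-122-5p	0.000473464	10
serum	hsa-miR-34a-5p	3.75631e-7	1
serum	hsa-miR-192-5p	7.64172e-7	2
serum	hsa-miR-194-5p	2.61277e-5	3
serum	hsa-miR-215-5p	0.000294246	4
serum	hsa-miR-122-5p	0.00250717	5
serum	hsa-miR-193a-5p	0.004645046	6
serum	hsa-miR-193b-3p	0.012087665	7
serum	hsa-miR-485-3p	0.019741786	8
serum	hsa-miR-885-5p	0.022468769	9
serum	hsa-miR-10b-5p	0.035076107	10
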