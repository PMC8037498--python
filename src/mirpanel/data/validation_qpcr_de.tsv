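biofluid	feature	log2_fc	direction	p_adjusted	in_refined_signature
plasma	hsa-miR-34a-5p	3.14095	up	0.000072	1
plasma	hsa-miR-142-3p	-2.68394	down	0.000072	0
plasma	hsa-miR-107	-1.05870	down	0.000072	1
plasma	hsa-miR-363-3p	1.47048	up	0.000115	1
plasma	hsa-miR-193a-5p	2.86444	up	0.000115	1
plasma	hsa-miR-423-5p	1.48452	up	0.000209	1
plasma	hsa-miR-660-5p	1.36373	up	0.000285	0
plasma	hsa-miR-92a-3p	1.07172	up	0.000285	0
plasma	hsa-miR-378a-3p	1.84138	up	0.000419	0
plasma	hsa-miR-4732-5p	2.48124	up	0.000419	0
plasma	hsa-miR-501-3p	1.80138	up	0.000449	1
plasma	hsa-miR-486-5p	1.66803	up	0.000540	0
plasma	hsa-miR-502-3p	1.28134	up	0.001049	1
plasma	hsa-miR-215-5p	1.84928	up	0.001049	1
plasma	hsa-miR-411-5p	-1.45695	down	0.001049	1
plasma	hsa-miR-320a	1.27269	up	0.001196	1
plasma	hsa-miR-629-5p	1.46049	up	0.001413	1
plasma	hsa-miR-193b-3p	3.02042	up	0.001799	0
plasma	hsa-miR-10b-5p	1.4974	up	0.001838	1
plasma	hsa-miR-370-3p	-1.70755	down	0.003432	0
plasma	hsa-miR-885-5p	2.89025	up	0.004502	0
plasma	hsa-miR-192-5p	1.60991	up	0.005376	1
plasma	hsa-miR-183-5p	1.60648	up	0.005376	0
plasma	hsa-miR-874-3p	1.15817	up	0.006205	1
plasma	hsa-miR-122-5p	2.83981	up	0.008159	1
plasma	hsa-miR-194-5p	1.67026	up	0.008929	0
plasma	hsa-miR-340-3p	-1.65444	down	0.008929	1
plasma	hsa-miR-1180-3p	1.61073	up	0.010158	0
plasma	hsa-let-7b-3p	1.04539	up	0.013040	1
plasma	hsa-miR-483-5p	2.97892	up	0.014706	0
plasma	hsa-miR-486-3p	1.21158	up	0.016641	0
plasma	hsa-miR-199a-5p	-1.34595	down	0.022482	0
plasma	hsa-miR-1285-3p	1.54743	up	0.031837	0
serum	hsa-miR-215-5p	1.23468	up	0.023866	0
serum	hsa-miR-34a-5p	1.50986	up	0.025611	0
serum	hsa-miR-192-5p	1.02344	up	0.026616	0
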