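stratum	feature	mean_disease_tmm	mean_healthy_tmm	log2_fc	p_raw	p_adjusted
le19	hsa-miR-215-5p	183	6	4.60	0.0001	0.0211
20_29	hsa-miR-451a	14019	4301	1.70	0.0001	0.0004
20_29	hsa-miR-32-5p	227	39	2.52	0.0001	0.0028
20_29	hsa-miR-363-3p	315	99	1.66	0.0001	0.0028
20_29	hsa-miR-501-3p	274	91	1.56	0.0001	0.0028
20_29	hsa-miR-194-5p	588	203	1.53	0.0001	0.0028
20_29	hsa-miR-502-3p	69	18	1.89	0.0001	0.0028
20_29	hsa-miR-4732-5p	1927	320	2.59	0.0001	0.0029
20_29	hsa-miR-214-3p	14	1	2.84	0.0001	0.0030
20_29	hsa-miR-210-3p	34	8	1.98	0.0001	0.0030
20_29	hsa-miR-107	866	236	1.88	0.0001	0.0030
20_29	hsa-miR-22-3p	1239	362	1.77	0.0001	0.0040
20_29	hsa-miR-34a-5p	82	21	1.93	0.0002	0.0060
20_29	hsa-miR-106b-5p	43	13	1.68	0.0002	0.0060
20_29	hsa-miR-942-5p	149	69	1.09	0.0002	0.0060
20_29	hsa-miR-192-5p	991	376	1.40	0.0003	0.0075
20_29	hsa-miR-486-5p	262731	103131	1.35	0.0004	0.0086
20_29	hsa-miR-130b-3p	108	33	1.69	0.0004	0.0089
20_29	hsa-miR-16-5p	360834	151980	1.25	0.0005	0.0099
20_29	hsa-miR-15a-5p	800	256	1.64	0.0006	0.0108
20_29	hsa-miR-660-5p	751	332	1.17	0.0006	0.0110
20_29	hsa-miR-1285-3p	7	0	4.77	0.0008	0.0121
20_29	hsa-miR-484	1831	647	1.50	0.0007	0.0121
20_29	hsa-miR-182-5p	1745	632	1.46	0.0008	0.0121
20_29	hsa-miR-378a-3p	247	121	1.02	0.0010	0.0146
20_29	hsa-miR-183-5p	1230	459	1.42	0.0017	0.0225
20_29	hsa-miR-1224-5p	83	19	2.16	0.0019	0.0237
20_29	hsa-miR-320a	9249	3080	1.59	0.0019	0.0237
20_29	hsa-miR-629-5p	618	261	1.24	0.0019	0.0237
20_29	hsa-miR-503-5p	55	23	1.23	0.0023	0.0258
20_29	hsa-miR-92a-3p	53636	25118	1.09	0.0023	0.0258
20_29	hsa-miR-3613-5p	182	57	1.66	0.0028	0.0296
20_29	hsa-miR-483-5p	1689	579	1.54	0.0030	0.0296
20_29	hsa-miR-4467	13	1	3.15	0.0033	0.0323
20_29	hsa-miR-423-5p	82538	33034	1.32	0.0035	0.0330
20_29	hsa-miR-6805-5p	16	3	2.21	0.0047	0.0404
20_29	hsa-miR-450a-2-3p	4	0	2.50	0.0049	0.0408
20_29	hsa-miR-101-3p	1911	886	1.11	0.0051	0.0420
20_29	hsa-miR-1294	70	30	1.20	0.0053	0.0422
20_29	hsa-miR-15b-5p	1428	703	1.02	0.0053	0.0422
20_29	hsa-miR-1180-3p	232	98	1.24	0.0060	0.0452
20_29	hsa-miR-486-3p	225	102	1.13	0.0065	0.0460
20_29	hsa-miR-885-5p	60	13	2.15	0.0071	0.0494
ge30	hsa-miR-483-5p	2391	478	2.32	0.0001	0.0031
ge30	hsa-miR-215-5p	142	37	1.97	0.0001	0.0034
ge30	hsa-miR-34a-5p	108	31	1.75	0.0001	0.0034
ge30	hsa-let-7b-3p	45	14	1.60	0.0001	0.0034
ge30	hsa-miR-192-5p	1150	487	1.24	0.0001	0.0043
ge30	hsa-miR-193b-3p	9	0	4.84	0.0001	0.0053
ge30	hsa-miR-193b-5p	199	51	1.96	0.0002	0.0053
ge30	hsa-miR-193a-5p	1001	409	1.29	0.0002	0.0054
ge30	hsa-miR-214-3p	27	5	2.56	0.0003	0.0084
ge30	hsa-miR-206	928	145	2.67	0.0004	0.0085
ge30	hsa-miR-125b-5p	2115	989	1.09	0.0003	0.0085
ge30	hsa-miR-194-5p	618	259	1.25	0.0006	0.0128
ge30	hsa-miR-122-5p	160505	52033	1.63	0.0007	0.0137
ge30	hsa-miR-10b-5p	1093	514	1.09	0.0007	0.0137
ge30	hsa-miR-885-3p	156	40	1.94	0.0010	0.0202
ge30	hsa-miR-874-3p	86	38	1.19	0.0020	0.0346
ge30	hsa-miR-4467	15	2	2.86	0.0026	0.0412
ge30	hsa-miR-423-5p	59588	33945	0.81	0.0028	0.0432
20_29	hsa-miR-181c-3p	2	26	-3.09	0.0001	0.0004
20_29	hsa-miR-1301-3p	66	172	-1.36	0.0001	0.0028
20_29	hsa-miR-142-3p	3476	7917	-1.19	0.0002	0.0050
20_29	hsa-miR-5193	0	7	-3.66	0.0002	0.0060
20_29	hsa-miR-744-5p	546	1169	-1.10	0.0005	0.0106
20_29	hsa-miR-582-3p	3	15	-2.32	0.0006	0.0108
20_29	hsa-miR-3168	0	6	-3.37	0.0008	0.0121
20_29	hsa-miR-151a-5p	84	182	-1.09	0.0013	0.0179
20_29	hsa-miR-873-5p	0	4	-3.85	0.0028	0.0296
20_29	hsa-miR-340-3p	3	12	-2.16	0.0037	0.0330
20_29	hsa-miR-7849-3p	1	6	-2.55	0.0044	0.0385
20_29	hsa-miR-4433b-5p	327	949	-1.54	0.0059	0.0450
20_29	hsa-miR-31-5p	2	11	-2.21	0.0061	0.0456
20_29	hsa-miR-6721-5p	10	32	-1.62	0.0065	0.0460
ge30	hsa-miR-487b-3p	11	64	-2.42	0.0001	0.0005
ge30	hsa-miR-370-3p	55	235	-2.07	0.0001	0.0013
ge30	hsa-miR-485-3p	114	492	-2.12	0.0001	0.0013
ge30	hsa-miR-485-5p	28	87	-1.65	0.0001	0.0034
ge30	hsa-miR-412-5p	0	9	-3.57	0.0001	0.0051
ge30	hsa-miR-411-5p	7	41	-2.35	0.0002	0.0053
ge30	hsa-miR-6767-5p	0	6	-4.30	0.0004	0.0085
ge30	hsa-miR-362-5p	0	5	-4.15	0.0011	0.0203
ge30	hsa-miR-409-3p	626	1788	-1.51	0.0017	0.0307
ge30	hsa-miR-30d-3p	0	6	-2.91	0.0031	0.0458
ge30	hsa-miR-199a-5p	31	67	-1.02	0.0035	0.0498
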