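locus	allele	n_affected	n_control	p	or	ci_low	ci_high	significant
DQA1	00101	43	69	0.1402	1.57	0.86	2.86	0
DQA1	00901	8	38	0.0087	0.33	0.14	0.76	1
DQA1	00601	13	16	0.1865	1.71	0.77	3.81	0
DQA1	00201	1	5	0.3804	0.38	0.04	3.31	0
DQA1	00301	1	3	0.7033	0.64	0.06	6.29	0
DQA1	00401	0	1	0.7854	0.64	0.03	15.92	0
DQA1	005011	1	0	0.2796	5.89	0.24	146.51	0
DQA1	00801	1	0	0.2796	5.89	0.24	146.51	0
DQB1	C1	22	37	0.5257	1.23	0.65	2.32	0
DQB1	00101	8	40	0.0050	0.31	0.13	0.70	1
DQB1	00201	21	25	0.0594	1.91	0.97	3.75	0
DQB1	02301	9	15	0.6999	1.19	0.49	2.88	0
DQB1	01303	1	5	0.3804	0.38	0.04	3.31	0
DQB1	00802	0	5	0.2314	0.17	0.01	3.11	0
DQB1	00401	1	3	0.7033	0.64	0.07	6.29	0
DQB1	02002	1	1	0.6373	1.96	0.12	31.75	0
DQB1	00301	3	0	0.0811	14.16	0.72	278.23	0
DQB1	00701	1	0	0.2796	5.89	0.24	146.51	0
DQB1	00502	1	0	0.2796	5.89	0.24	146.51	0
DQB1	01701	0	1	0.7854	0.64	0.03	15.92	0
DRB1	U	20	25	0.0952	1.78	0.90	3.52	0
DRB1	T	7	31	0.0284	0.37	0.16	0.90	1
DRB1	Z	5	23	0.0592	0.38	0.14	1.04	0
DRB1	09401	14	8	0.0032	4.02	1.59	10.14	1
DRB1	01502	6	10	0.7582	1.18	0.41	3.40	0
DRB1	00203	2	13	0.0980	0.28	0.06	1.27	0
DRB1	W	6	8	0.4706	1.50	0.50	4.51	0
DRB1	04801	1	5	0.3804	0.38	0.04	3.31	0
DRB1	01701	0	4	0.2952	0.21	0.01	3.93	0
DRB1	07301	1	1	0.6373	1.96	0.12	31.75	0
DRB1	DH-Davis	1	1	0.6373	1.96	0.12	31.75	0
DRB1	01503	1	0	0.2796	5.89	0.24	146.51	0
DRB1	02901	0	1	0.7854	0.64	0.03	15.92	0
DRB1	0802	0	1	0.7854	0.64	0.03	15.92	0
DRB1	102:01	1	0	0.2796	5.89	0.24	146.51	0
DRB1	01301	1	0	0.2796	5.89	0.24	146.51	0
DRB1	01504	1	0	0.2796	5.89	0.24	146.51	0
DRB1	01201	0	1	0.7854	0.64	0.03	15.92	0
DRB1	EH-13	1	0	0.2796	5.89	0.24	146.51	0
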