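haplotype	n_affected	n_control	p	or	ci_low	ci_high	significant
U/00101/00201	20	25	0.0952	1.78	0.90	3.52	0
T/00101/C1	7	29	0.0466	0.41	0.17	0.99	1
Z/00901/00101	5	23	0.0592	0.38	0.14	1.04	0
09401/00101/C1	14	8	0.0032	4.02	1.59	10.14	1
01502/00601/02301	6	10	0.7582	1.18	0.41	3.40	0
00203/00901/00101	2	13	0.0980	0.28	0.06	1.27	0
W/00601/02301	1	5	0.3804	0.38	0.04	3.31	0
04801/00101/00802	0	5	0.2314	0.17	0.01	3.11	0
01701/00201/01303	0	4	0.2952	0.21	0.01	3.93	0
W/00901/00101	1	2	0.9804	0.97	0.09	10.89	0
W/00601/02002	1	1	0.6373	1.96	0.12	31.75	0
W/00601/00301	3	0	0.0811	14.16	0.72	278.23	0
T/00101/00101	0	2	0.5353	0.38	0.02	8.05	0
DH-Davis/00301/00401	1	1	0.6373	1.96	0.12	31.75	0
07301/00201/01303	1	1	0.6373	1.96	0.12	31.75	0
01201/00401/01701	0	1	0.7854	0.64	0.03	15.92	0
02901/00301/00401	0	1	0.7854	0.64	0.03	15.92	0
0802/00301/00401	0	1	0.7854	0.64	0.03	15.92	0
102:01/00101/00201	1	0	0.2796	5.89	0.24	146.51	0
01504/00601/02301	1	0	0.2796	5.89	0.24	146.51	0
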