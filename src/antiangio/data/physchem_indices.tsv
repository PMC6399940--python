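index_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
side_chain_mass	15.0	47.0	59.0	73.0	91.0	1.0	82.0	57.0	73.0	57.0	75.0	58.0	42.0	72.0	101.0	31.0	45.0	43.0	130.0	107.0
hydropathy_kd	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
residue_mass	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.10	97.12	128.13	156.19	87.08	101.10	99.13	186.21	163.18
isoelectric_point	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
residue_volume	88.6	108.5	111.1	138.4	189.9	60.1	153.2	166.7	168.6	166.7	162.9	114.1	112.7	143.8	173.4	89.0	116.1	140.0	227.8	193.6
polarity_grantham	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
net_charge_ph7	0.0	0.0	-1.0	-1.0	0.0	0.0	0.1	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
hydrophobicity_fp	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
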