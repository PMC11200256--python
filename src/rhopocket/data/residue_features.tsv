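res	acid_base_acidic	acid_base_basic	acid_base_neutral	neutral5_aliphatic	neutral5_aromatic	neutral5_polar	neutral5_cysteine	neutral5_progly	neutral2_polar	hydropathy	hydrophobic	isoelectric_point	logp	mol_weight	organic_value	inorganic_value	polarity_index	residue_volume
ALA	0	0	1	1	0	0	0	0	0	1.8	1	6.00	0.31	89.1	60	60	8.1	88.6
ARG	0	1	0	0	0	0	0	0	0	-4.5	0	10.76	-1.01	174.2	120	360	10.5	173.4
ASN	0	0	1	0	0	1	0	0	1	-3.5	0	5.41	-0.60	132.1	80	260	11.6	114.1
ASP	1	0	0	0	0	0	0	0	0	-3.5	0	2.77	-0.77	133.1	80	260	13.0	111.1
CYS	0	0	1	0	0	0	1	0	1	2.5	1	5.07	1.54	121.2	60	160	5.5	108.5
GLN	0	0	1	0	0	1	0	0	1	-3.5	0	5.65	-0.22	146.2	100	260	10.5	143.8
GLU	1	0	0	0	0	0	0	0	0	-3.5	0	3.22	-0.64	147.1	100	260	12.3	138.4
GLY	0	0	1	0	0	0	0	1	0	-0.4	0	5.97	0.00	75.1	40	60	9.0	60.1
HIS	0	1	0	0	0	0	0	0	0	-3.2	0	7.59	0.13	155.2	120	260	10.4	153.2
ILE	0	0	1	1	0	0	0	0	0	4.5	1	6.02	1.80	131.2	120	60	5.2	166.7
LEU	0	0	1	1	0	0	0	0	0	3.8	1	5.98	1.70	131.2	120	60	4.9	166.7
LYS	0	1	0	0	0	0	0	0	0	-3.9	0	9.74	-0.99	146.2	120	160	11.3	168.6
MET	0	0	1	1	0	0	0	0	0	1.9	1	5.74	1.23	149.2	100	160	5.7	162.9
PHE	0	0	1	0	1	0	0	0	0	2.8	1	5.48	1.79	165.2	180	60	5.2	189.9
PRO	0	0	1	0	0	0	0	1	0	-1.6	0	6.30	0.72	115.1	100	60	8.0	112.7
SER	0	0	1	0	0	1	0	0	1	-0.8	0	5.68	-0.04	105.1	60	160	9.2	89.0
THR	0	0	1	0	0	1	0	0	1	-0.7	0	5.60	0.26	119.1	80	160	8.6	116.1
TRP	0	0	1	0	1	0	0	0	0	-0.9	0	5.89	2.25	204.2	220	160	5.4	227.8
TYR	0	0	1	0	1	0	0	0	1	-1.3	0	5.66	0.96	181.2	180	160	6.2	193.6
VAL	0	0	1	1	0	0	0	0	0	4.2	1	5.96	1.22	117.1	100	60	5.9	140.0
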