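property_name	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	provenance
ASA	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230	Accessible surface area in Gly-X-Gly tripeptide (Chothia 1976)
charge	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0	Net side-chain charge at physiological pH (Asp/Glu -1, Lys/Arg +1)
ECI	0.05	0.15	1.25	1.31	0.14	0.02	0.56	0.09	0.53	0.10	0.34	1.36	0.16	1.31	1.69	0.56	0.65	0.07	1.08	0.72	Electronic charge index of side chain (Collantes & Dunn 1995)
entropy	0	1	2	3	2	0	2	2	4	2	3	2	0	3	4	1	1	1	2	2	Side-chain rotatable-bond count, a conformational-entropy proxy; override with a published entropy-of-formation scale for exact reproduction
hydrophobicity	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3	Kyte-Doolittle hydropathy index (Kyte & Doolittle 1982)
ISA	62.90	78.51	18.46	30.19	189.42	19.93	87.38	149.77	102.78	154.35	132.22	19.53	122.35	17.87	52.98	19.75	59.44	120.91	179.16	132.16	Isotropic surface area of side chain (Collantes & Dunn 1995)
Mw	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.10	97.12	128.13	156.19	87.08	101.10	99.13	186.21	163.18	Monoisotopic-adjacent average residue mass (Da)
organic_solvent_water	0.5	0.0	0.0	0.0	2.5	0.0	0.5	1.8	0.0	1.8	1.3	0.0	1.4	0.0	0.0	0.0	0.4	1.5	3.4	2.3	Transfer free energy water to organic solvent, kcal/mol (Nozaki & Tanford 1971)
PI	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66	Isoelectric point of free amino acid (Zimmerman 1968)
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2	Polarity (Grantham 1974)
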