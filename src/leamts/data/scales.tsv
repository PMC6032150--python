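# Hydrophobicity scale registry: scale_id, then one value per residue.
# fauchere_pliska: octanol/water side-chain transfer free energies
# (Fauchere & Pliska 1983), the scale used by helical-wheel projection
# servers for hydrophobic-moment arrows.
# kyte_doolittle: Kyte & Doolittle (1982) hydropathy index.
# eisenberg: Eisenberg et al. (1984) normalized consensus scale.
scale	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
fauchere_pliska	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
kyte_doolittle	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
eisenberg	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
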