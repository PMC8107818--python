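compound_id	name	cas	retention_time_min	pct_total
c01	Beta-myrcene		6.1048	9.642
c02	3-Carene		7.1052	7.549
c03	Beta-ocimene		7.5053	6.203
c04	Linalool		9.0309	21.999
c05	1-Octen-3-yl-acetate		9.0725	1.254
c06	2,4,6-Octatriene, 3,4-dimethyl-		9.4144	4.91
c07	2,4,6-Octatriene, 2,6-dimethyl-, (E,Z)-		9.6728	0.746
c08	4-Hexen-1-ol, 5-methyl-2-(1-methylethenyl)-, (R)-		10.2980	2.198
c09	3-Cyclohexen-1-ol, 4-methyl-1-(1-methylethyl)-, (R)-		10.5565	5.981
c10	Butanoic acid, hexyl ester		10.6231	1.057
c11	Alpha-terpineol		10.8399	2.426
c12	Tricyclo [2.2.1.0 (2,6)]heptane, 1,3,3-trimethyl-		11.9070	16.095
c13	4-Hexen-1-ol, 5-methyl-2-(1-methylethenyl)-, acetate		12.3905	4.334
c14	2,6-Octadien-1-ol, 3,7-dimethyl-, acetate, (Z)-		13.5159	2.155
c15	Geranyl acetate		13.8077	3.097
c16	Tricyclo [2.2.1.0 (2,6)]heptane, 1,7-dimethyl-7-(4-methyl-3-pentenyl)-, (-)-		14.3912	0.995
c17	Caryophyllene		14.4663	4.627
c18	(E)-beta-farnesene		14.8247	3.94
c19	Caryophyllene oxide		16.6587	0.792
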