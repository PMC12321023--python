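# Displaced solvent volumes [A^3] for implicit-hydrogen atomic groups,
# built from the classical Traube-derived atomic volumes
# (C 16.44, H 5.15, N 2.49, O 9.13, S 19.86, P 5.73 A^3) by summation.
# No uncertainties were reported for these historical values.
# species	volume	uncertainty
C	16.44	0
N	2.49	0
O	9.13	0
S	19.86	0
P	5.73	0
SE	28.73	0
CH	21.59	0
CH2	26.74	0
CH3	31.89	0
NH	7.64	0
NH2	12.79	0
NH3	17.94	0
OH	14.28	0
SH	25.01	0
H2O	30.00	0
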