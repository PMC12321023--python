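# SYNTHETIC stand-in table: representative minimum-fluctuation-style group
# volumes [A^3] for implicit-hydrogen atomic groups. The genuine literature
# table could not be bundled; these values are constructed to lie in the
# range of published protein-interior group volumes and carry ~10%
# uncertainties, which is the property the package exercises.
# species	volume	uncertainty
C	9.7	1.0
N	8.0	0.8
O	16.0	1.6
S	25.2	2.5
P	11.0	1.1
SE	28.0	2.8
CH	21.1	2.1
CH2	24.3	2.4
CH3	35.3	3.5
NH	14.2	1.4
NH2	22.0	2.2
NH3	26.0	2.6
OH	18.2	1.8
SH	34.0	3.4
H2O	30.0	3.0
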