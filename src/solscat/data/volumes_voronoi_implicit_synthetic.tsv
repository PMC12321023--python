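# SYNTHETIC stand-in table: representative Voronoi-tessellation-style group
# volumes [A^3] for implicit-hydrogen atomic groups (protein-interior
# averages). See the minimum-fluctuation file header for provenance.
# species	volume	uncertainty
C	10.6	1.1
N	9.0	0.9
O	15.9	1.6
S	24.4	2.4
P	12.0	1.2
SE	29.0	2.9
CH	20.4	2.0
CH2	23.5	2.4
CH3	36.7	3.7
NH	15.4	1.5
NH2	23.2	2.3
NH3	27.5	2.8
OH	17.9	1.8
SH	33.2	3.3
H2O	30.0	3.0
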