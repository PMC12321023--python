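# SYNTHETIC stand-in table: representative Voronoi-style volumes [A^3] per
# element for explicit-hydrogen structures.
# species	volume	uncertainty
H	5.1	0.5
C	14.8	1.5
N	8.2	0.8
O	13.1	1.3
S	22.0	2.2
P	9.5	1.0
SE	25.5	2.6
H2O	30.0	3.0
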