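# SYNTHETIC stand-in table: representative minimum-fluctuation-style volumes
# [A^3] per element for explicit-hydrogen structures. Heavy-atom volumes are
# smaller than the corresponding implicit-hydrogen group volumes to make
# room for the explicitly placed hydrogens.
# species	volume	uncertainty
H	5.2	0.5
C	14.0	1.4
N	7.5	0.8
O	12.8	1.3
S	21.5	2.2
P	9.0	0.9
SE	25.0	2.5
H2O	30.0	3.0
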