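# Displaced solvent volumes [A^3] per element for explicit-hydrogen
# structures, classical Traube-derived atomic volumes.
# species	volume	uncertainty
H	5.15	0
C	16.44	0
N	2.49	0
O	9.13	0
S	19.86	0
P	5.73	0
SE	28.73	0
H2O	30.00	0
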