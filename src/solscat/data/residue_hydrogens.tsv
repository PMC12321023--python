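# Covalently bound hydrogens per (residue, atom) for in-chain residues.
# Backbone amide N counts are already reduced by one hydrogen relative to the
# free amino acid, reflecting the peptide-bond context; no extra terminal
# hydrogen is added. Acidic side chains carry their acid proton (neutral ASP,
# GLU), HIS is the neutral ND1-H tautomer, LYS and ARG are protonated.
# residue	atom	n_h
ALA	N	1
ALA	CA	1
ALA	C	0
ALA	O	0
ALA	CB	3
ARG	N	1
ARG	CA	1
ARG	C	0
ARG	O	0
ARG	CB	2
ARG	CG	2
ARG	CD	2
ARG	NE	1
ARG	CZ	0
ARG	NH1	2
ARG	NH2	2
ASN	N	1
ASN	CA	1
ASN	C	0
ASN	O	0
ASN	CB	2
ASN	CG	0
ASN	OD1	0
ASN	ND2	2
ASP	N	1
ASP	CA	1
ASP	C	0
ASP	O	0
ASP	CB	2
ASP	CG	0
ASP	OD1	0
ASP	OD2	1
CYS	N	1
CYS	CA	1
CYS	C	0
CYS	O	0
CYS	CB	2
CYS	SG	1
GLN	N	1
GLN	CA	1
GLN	C	0
GLN	O	0
GLN	CB	2
GLN	CG	2
GLN	CD	0
GLN	OE1	0
GLN	NE2	2
GLU	N	1
GLU	CA	1
GLU	C	0
GLU	O	0
GLU	CB	2
GLU	CG	2
GLU	CD	0
GLU	OE1	0
GLU	OE2	1
GLY	N	1
GLY	CA	2
GLY	C	0
GLY	O	0
HIS	N	1
HIS	CA	1
HIS	C	0
HIS	O	0
HIS	CB	2
HIS	CG	0
HIS	ND1	1
HIS	CD2	1
HIS	CE1	1
HIS	NE2	0
ILE	N	1
ILE	CA	1
ILE	C	0
ILE	O	0
ILE	CB	1
ILE	CG1	2
ILE	CG2	3
ILE	CD1	3
LEU	N	1
LEU	CA	1
LEU	C	0
LEU	O	0
LEU	CB	2
LEU	CG	1
LEU	CD1	3
LEU	CD2	3
LYS	N	1
LYS	CA	1
LYS	C	0
LYS	O	0
LYS	CB	2
LYS	CG	2
LYS	CD	2
LYS	CE	2
LYS	NZ	3
MET	N	1
MET	CA	1
MET	C	0
MET	O	0
MET	CB	2
MET	CG	2
MET	SD	0
MET	CE	3
PHE	N	1
PHE	CA	1
PHE	C	0
PHE	O	0
PHE	CB	2
PHE	CG	0
PHE	CD1	1
PHE	CD2	1
PHE	CE1	1
PHE	CE2	1
PHE	CZ	1
PRO	N	0
PRO	CA	1
PRO	C	0
PRO	O	0
PRO	CB	2
PRO	CG	2
PRO	CD	2
SER	N	1
SER	CA	1
SER	C	0
SER	O	0
SER	CB	2
SER	OG	1
THR	N	1
THR	CA	1
THR	C	0
THR	O	0
THR	CB	1
THR	OG1	1
THR	CG2	3
TRP	N	1
TRP	CA	1
TRP	C	0
TRP	O	0
TRP	CB	2
TRP	CG	0
TRP	CD1	1
TRP	CD2	0
TRP	NE1	1
TRP	CE2	0
TRP	CE3	1
TRP	CZ2	1
TRP	CZ3	1
TRP	CH2	1
TYR	N	1
TYR	CA	1
TYR	C	0
TYR	O	0
TYR	CB	2
TYR	CG	0
TYR	CD1	1
TYR	CD2	1
TYR	CE1	1
TYR	CE2	1
TYR	CZ	0
TYR	OH	1
VAL	N	1
VAL	CA	1
VAL	C	0
VAL	O	0
VAL	CB	1
VAL	CG1	3
VAL	CG2	3
HOH	O	2
# Nucleotides (in-chain, ionized phosphodiester backbone: no phosphate H).
A	P	0
A	OP1	0
A	OP2	0
A	O5'	0
A	C5'	2
A	C4'	1
A	O4'	0
A	C3'	1
A	O3'	0
A	C2'	1
A	O2'	1
A	C1'	1
A	N9	0
A	C8	1
A	N7	0
A	C5	0
A	C6	0
A	N6	2
A	N1	0
A	C2	1
A	N3	0
A	C4	0
G	P	0
G	OP1	0
G	OP2	0
G	O5'	0
G	C5'	2
G	C4'	1
G	O4'	0
G	C3'	1
G	O3'	0
G	C2'	1
G	O2'	1
G	C1'	1
G	N9	0
G	C8	1
G	N7	0
G	C5	0
G	C6	0
G	O6	0
G	N1	1
G	C2	0
G	N2	2
G	N3	0
G	C4	0
C	P	0
C	OP1	0
C	OP2	0
C	O5'	0
C	C5'	2
C	C4'	1
C	O4'	0
C	C3'	1
C	O3'	0
C	C2'	1
C	O2'	1
C	C1'	1
C	N1	0
C	C2	0
C	O2	0
C	N3	0
C	C4	0
C	N4	2
C	C5	1
C	C6	1
U	P	0
U	OP1	0
U	OP2	0
U	O5'	0
U	C5'	2
U	C4'	1
U	O4'	0
U	C3'	1
U	O3'	0
U	C2'	1
U	O2'	1
U	C1'	1
U	N1	0
U	C2	0
U	O2	0
U	N3	1
U	C4	0
U	O4	0
U	C5	1
U	C6	1
DA	P	0
DA	OP1	0
DA	OP2	0
DA	O5'	0
DA	C5'	2
DA	C4'	1
DA	O4'	0
DA	C3'	1
DA	O3'	0
DA	C2'	2
DA	C1'	1
DA	N9	0
DA	C8	1
DA	N7	0
DA	C5	0
DA	C6	0
DA	N6	2
DA	N1	0
DA	C2	1
DA	N3	0
DA	C4	0
DG	P	0
DG	OP1	0
DG	OP2	0
DG	O5'	0
DG	C5'	2
DG	C4'	1
DG	O4'	0
DG	C3'	1
DG	O3'	0
DG	C2'	2
DG	C1'	1
DG	N9	0
DG	C8	1
DG	N7	0
DG	C5	0
DG	C6	0
DG	O6	0
DG	N1	1
DG	C2	0
DG	N2	2
DG	N3	0
DG	C4	0
DC	P	0
DC	OP1	0
DC	OP2	0
DC	O5'	0
DC	C5'	2
DC	C4'	1
DC	O4'	0
DC	C3'	1
DC	O3'	0
DC	C2'	2
DC	C1'	1
DC	N1	0
DC	C2	0
DC	O2	0
DC	N3	0
DC	C4	0
DC	N4	2
DC	C5	1
DC	C6	1
DT	P	0
DT	OP1	0
DT	OP2	0
DT	O5'	0
DT	C5'	2
DT	C4'	1
DT	O4'	0
DT	C3'	1
DT	O3'	0
DT	C2'	2
DT	C1'	1
DT	N1	0
DT	C2	0
DT	O2	0
DT	N3	1
DT	C4	0
DT	O4	0
DT	C5	0
DT	C7	3
DT	C6	1
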