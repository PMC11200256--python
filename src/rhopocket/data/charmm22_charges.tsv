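res	atom	charge
*	N	-0.47
*	CA	0.07
*	C	0.51
*	O	-0.51
*	OXT	-0.67
GLY	CA	-0.02
PRO	N	-0.29
PRO	CA	0.02
PRO	CD	0.00
ALA	CB	-0.27
SER	CB	0.05
SER	OG	-0.66
CYS	CB	-0.11
CYS	SG	-0.23
THR	CB	0.14
THR	OG1	-0.66
THR	CG2	-0.27
VAL	CB	-0.09
VAL	CG1	-0.27
VAL	CG2	-0.27
LEU	CB	-0.18
LEU	CG	-0.09
LEU	CD1	-0.27
LEU	CD2	-0.27
ILE	CB	-0.09
ILE	CG1	-0.18
ILE	CG2	-0.27
ILE	CD1	-0.27
MET	CB	-0.18
MET	CG	-0.14
MET	SD	-0.09
MET	CE	-0.22
PRO	CB	-0.18
PRO	CG	-0.18
PHE	CB	-0.18
PHE	CG	0.00
PHE	CD1	-0.115
PHE	CD2	-0.115
PHE	CE1	-0.115
PHE	CE2	-0.115
PHE	CZ	-0.115
TYR	CB	-0.18
TYR	CG	0.00
TYR	CD1	-0.115
TYR	CD2	-0.115
TYR	CE1	-0.115
TYR	CE2	-0.115
TYR	CZ	0.11
TYR	OH	-0.54
TRP	CB	-0.18
TRP	CG	-0.03
TRP	CD1	0.035
TRP	CD2	-0.02
TRP	NE1	-0.61
TRP	CE2	0.13
TRP	CE3	-0.115
TRP	CZ2	-0.115
TRP	CZ3	-0.115
TRP	CH2	-0.115
ASP	CB	-0.28
ASP	CG	0.62
ASP	OD1	-0.76
ASP	OD2	-0.76
GLU	CB	-0.18
GLU	CG	-0.28
GLU	CD	0.62
GLU	OE1	-0.76
GLU	OE2	-0.76
ASN	CB	-0.18
ASN	CG	0.55
ASN	OD1	-0.55
ASN	ND2	-0.62
GLN	CB	-0.18
GLN	CG	-0.18
GLN	CD	0.55
GLN	OE1	-0.55
GLN	NE2	-0.62
HIS	CB	-0.09
HIS	CG	-0.05
HIS	ND1	-0.36
HIS	CD2	0.22
HIS	CE1	0.25
HIS	NE2	-0.70
LYS	CB	-0.18
LYS	CG	-0.18
LYS	CD	-0.18
LYS	CE	0.21
LYS	NZ	-0.30
ARG	CB	-0.18
ARG	CG	-0.18
ARG	CD	0.20
ARG	NE	-0.70
ARG	CZ	0.64
ARG	NH1	-0.80
ARG	NH2	-0.80
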