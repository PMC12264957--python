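# airdock heavy-atom force field parameter table, version 1
# columns (tab-separated):
#   residue  three-letter residue code
#   atom     PDB heavy-atom name
#   epsilon  Lennard-Jones well depth, kcal/mol (combined geometrically)
#   rmin     Lennard-Jones pair minimum for two like atoms, Å (combined
#            arithmetically: rmin_ij = (rmin_i + rmin_j)/2)
#   charge   formal partial charge, e (integer-summing per residue; chain
#            termini patched at topology build time)
#   asp      atomic solvation parameter, kcal/mol/Å² (desolvation energy =
#            sum of asp_i * ΔSASA_i on complexation)
#   radius   atomic radius for solvent-accessible surface area, Å
ALA	N	0.160	3.50	0.00	-0.0600	1.70
ALA	CA	0.105	4.00	0.00	0.0125	1.90
ALA	C	0.105	4.00	0.00	0.0125	1.90
ALA	O	0.210	3.20	0.00	-0.0600	1.50
ALA	CB	0.105	4.00	0.00	0.0125	1.90
ARG	N	0.160	3.50	0.00	-0.0600	1.70
ARG	CA	0.105	4.00	0.00	0.0125	1.90
ARG	C	0.105	4.00	0.00	0.0125	1.90
ARG	O	0.210	3.20	0.00	-0.0600	1.50
ARG	CB	0.105	4.00	0.00	0.0125	1.90
ARG	CG	0.105	4.00	0.00	0.0125	1.90
ARG	CD	0.105	4.00	0.00	0.0125	1.90
ARG	NE	0.160	3.50	0.00	-0.1200	1.70
ARG	CZ	0.105	4.00	0.00	0.0125	1.90
ARG	NH1	0.160	3.50	0.50	-0.1200	1.70
ARG	NH2	0.160	3.50	0.50	-0.1200	1.70
ASN	N	0.160	3.50	0.00	-0.0600	1.70
ASN	CA	0.105	4.00	0.00	0.0125	1.90
ASN	C	0.105	4.00	0.00	0.0125	1.90
ASN	O	0.210	3.20	0.00	-0.0600	1.50
ASN	CB	0.105	4.00	0.00	0.0125	1.90
ASN	CG	0.105	4.00	0.00	0.0125	1.90
ASN	OD1	0.210	3.20	0.00	-0.0600	1.50
ASN	ND2	0.160	3.50	0.00	-0.0600	1.70
ASP	N	0.160	3.50	0.00	-0.0600	1.70
ASP	CA	0.105	4.00	0.00	0.0125	1.90
ASP	C	0.105	4.00	0.00	0.0125	1.90
ASP	O	0.210	3.20	0.00	-0.0600	1.50
ASP	CB	0.105	4.00	0.00	0.0125	1.90
ASP	CG	0.105	4.00	0.00	0.0125	1.90
ASP	OD1	0.210	3.20	-0.50	-0.1200	1.50
ASP	OD2	0.210	3.20	-0.50	-0.1200	1.50
CYS	N	0.160	3.50	0.00	-0.0600	1.70
CYS	CA	0.105	4.00	0.00	0.0125	1.90
CYS	C	0.105	4.00	0.00	0.0125	1.90
CYS	O	0.210	3.20	0.00	-0.0600	1.50
CYS	CB	0.105	4.00	0.00	0.0125	1.90
CYS	SG	0.250	3.90	0.00	0.0125	1.85
GLN	N	0.160	3.50	0.00	-0.0600	1.70
GLN	CA	0.105	4.00	0.00	0.0125	1.90
GLN	C	0.105	4.00	0.00	0.0125	1.90
GLN	O	0.210	3.20	0.00	-0.0600	1.50
GLN	CB	0.105	4.00	0.00	0.0125	1.90
GLN	CG	0.105	4.00	0.00	0.0125	1.90
GLN	CD	0.105	4.00	0.00	0.0125	1.90
GLN	OE1	0.210	3.20	0.00	-0.0600	1.50
GLN	NE2	0.160	3.50	0.00	-0.0600	1.70
GLU	N	0.160	3.50	0.00	-0.0600	1.70
GLU	CA	0.105	4.00	0.00	0.0125	1.90
GLU	C	0.105	4.00	0.00	0.0125	1.90
GLU	O	0.210	3.20	0.00	-0.0600	1.50
GLU	CB	0.105	4.00	0.00	0.0125	1.90
GLU	CG	0.105	4.00	0.00	0.0125	1.90
GLU	CD	0.105	4.00	0.00	0.0125	1.90
GLU	OE1	0.210	3.20	-0.50	-0.1200	1.50
GLU	OE2	0.210	3.20	-0.50	-0.1200	1.50
GLY	N	0.160	3.50	0.00	-0.0600	1.70
GLY	CA	0.105	4.00	0.00	0.0125	1.90
GLY	C	0.105	4.00	0.00	0.0125	1.90
GLY	O	0.210	3.20	0.00	-0.0600	1.50
HIS	N	0.160	3.50	0.00	-0.0600	1.70
HIS	CA	0.105	4.00	0.00	0.0125	1.90
HIS	C	0.105	4.00	0.00	0.0125	1.90
HIS	O	0.210	3.20	0.00	-0.0600	1.50
HIS	CB	0.105	4.00	0.00	0.0125	1.90
HIS	CG	0.105	4.00	0.00	0.0125	1.90
HIS	ND1	0.160	3.50	0.00	-0.0600	1.70
HIS	CD2	0.105	4.00	0.00	0.0125	1.90
HIS	CE1	0.105	4.00	0.00	0.0125	1.90
HIS	NE2	0.160	3.50	0.00	-0.0600	1.70
ILE	N	0.160	3.50	0.00	-0.0600	1.70
ILE	CA	0.105	4.00	0.00	0.0125	1.90
ILE	C	0.105	4.00	0.00	0.0125	1.90
ILE	O	0.210	3.20	0.00	-0.0600	1.50
ILE	CB	0.105	4.00	0.00	0.0125	1.90
ILE	CG1	0.105	4.00	0.00	0.0125	1.90
ILE	CG2	0.105	4.00	0.00	0.0125	1.90
ILE	CD1	0.105	4.00	0.00	0.0125	1.90
LEU	N	0.160	3.50	0.00	-0.0600	1.70
LEU	CA	0.105	4.00	0.00	0.0125	1.90
LEU	C	0.105	4.00	0.00	0.0125	1.90
LEU	O	0.210	3.20	0.00	-0.0600	1.50
LEU	CB	0.105	4.00	0.00	0.0125	1.90
LEU	CG	0.105	4.00	0.00	0.0125	1.90
LEU	CD1	0.105	4.00	0.00	0.0125	1.90
LEU	CD2	0.105	4.00	0.00	0.0125	1.90
LYS	N	0.160	3.50	0.00	-0.0600	1.70
LYS	CA	0.105	4.00	0.00	0.0125	1.90
LYS	C	0.105	4.00	0.00	0.0125	1.90
LYS	O	0.210	3.20	0.00	-0.0600	1.50
LYS	CB	0.105	4.00	0.00	0.0125	1.90
LYS	CG	0.105	4.00	0.00	0.0125	1.90
LYS	CD	0.105	4.00	0.00	0.0125	1.90
LYS	CE	0.105	4.00	0.00	0.0125	1.90
LYS	NZ	0.160	3.50	1.00	-0.1200	1.70
MET	N	0.160	3.50	0.00	-0.0600	1.70
MET	CA	0.105	4.00	0.00	0.0125	1.90
MET	C	0.105	4.00	0.00	0.0125	1.90
MET	O	0.210	3.20	0.00	-0.0600	1.50
MET	CB	0.105	4.00	0.00	0.0125	1.90
MET	CG	0.105	4.00	0.00	0.0125	1.90
MET	SD	0.250	3.90	0.00	0.0125	1.85
MET	CE	0.105	4.00	0.00	0.0125	1.90
PHE	N	0.160	3.50	0.00	-0.0600	1.70
PHE	CA	0.105	4.00	0.00	0.0125	1.90
PHE	C	0.105	4.00	0.00	0.0125	1.90
PHE	O	0.210	3.20	0.00	-0.0600	1.50
PHE	CB	0.105	4.00	0.00	0.0125	1.90
PHE	CG	0.105	4.00	0.00	0.0125	1.90
PHE	CD1	0.105	4.00	0.00	0.0125	1.90
PHE	CD2	0.105	4.00	0.00	0.0125	1.90
PHE	CE1	0.105	4.00	0.00	0.0125	1.90
PHE	CE2	0.105	4.00	0.00	0.0125	1.90
PHE	CZ	0.105	4.00	0.00	0.0125	1.90
PRO	N	0.160	3.50	0.00	-0.0600	1.70
PRO	CA	0.105	4.00	0.00	0.0125	1.90
PRO	C	0.105	4.00	0.00	0.0125	1.90
PRO	O	0.210	3.20	0.00	-0.0600	1.50
PRO	CB	0.105	4.00	0.00	0.0125	1.90
PRO	CG	0.105	4.00	0.00	0.0125	1.90
PRO	CD	0.105	4.00	0.00	0.0125	1.90
SER	N	0.160	3.50	0.00	-0.0600	1.70
SER	CA	0.105	4.00	0.00	0.0125	1.90
SER	C	0.105	4.00	0.00	0.0125	1.90
SER	O	0.210	3.20	0.00	-0.0600	1.50
SER	CB	0.105	4.00	0.00	0.0125	1.90
SER	OG	0.210	3.20	0.00	-0.0600	1.50
THR	N	0.160	3.50	0.00	-0.0600	1.70
THR	CA	0.105	4.00	0.00	0.0125	1.90
THR	C	0.105	4.00	0.00	0.0125	1.90
THR	O	0.210	3.20	0.00	-0.0600	1.50
THR	CB	0.105	4.00	0.00	0.0125	1.90
THR	OG1	0.210	3.20	0.00	-0.0600	1.50
THR	CG2	0.105	4.00	0.00	0.0125	1.90
TRP	N	0.160	3.50	0.00	-0.0600	1.70
TRP	CA	0.105	4.00	0.00	0.0125	1.90
TRP	C	0.105	4.00	0.00	0.0125	1.90
TRP	O	0.210	3.20	0.00	-0.0600	1.50
TRP	CB	0.105	4.00	0.00	0.0125	1.90
TRP	CG	0.105	4.00	0.00	0.0125	1.90
TRP	CD1	0.105	4.00	0.00	0.0125	1.90
TRP	CD2	0.105	4.00	0.00	0.0125	1.90
TRP	NE1	0.160	3.50	0.00	-0.0600	1.70
TRP	CE2	0.105	4.00	0.00	0.0125	1.90
TRP	CE3	0.105	4.00	0.00	0.0125	1.90
TRP	CZ2	0.105	4.00	0.00	0.0125	1.90
TRP	CZ3	0.105	4.00	0.00	0.0125	1.90
TRP	CH2	0.105	4.00	0.00	0.0125	1.90
TYR	N	0.160	3.50	0.00	-0.0600	1.70
TYR	CA	0.105	4.00	0.00	0.0125	1.90
TYR	C	0.105	4.00	0.00	0.0125	1.90
TYR	O	0.210	3.20	0.00	-0.0600	1.50
TYR	CB	0.105	4.00	0.00	0.0125	1.90
TYR	CG	0.105	4.00	0.00	0.0125	1.90
TYR	CD1	0.105	4.00	0.00	0.0125	1.90
TYR	CD2	0.105	4.00	0.00	0.0125	1.90
TYR	CE1	0.105	4.00	0.00	0.0125	1.90
TYR	CE2	0.105	4.00	0.00	0.0125	1.90
TYR	CZ	0.105	4.00	0.00	0.0125	1.90
TYR	OH	0.210	3.20	0.00	-0.0600	1.50
VAL	N	0.160	3.50	0.00	-0.0600	1.70
VAL	CA	0.105	4.00	0.00	0.0125	1.90
VAL	C	0.105	4.00	0.00	0.0125	1.90
VAL	O	0.210	3.20	0.00	-0.0600	1.50
VAL	CB	0.105	4.00	0.00	0.0125	1.90
VAL	CG1	0.105	4.00	0.00	0.0125	1.90
VAL	CG2	0.105	4.00	0.00	0.0125	1.90
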