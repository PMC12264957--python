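# free-residue reference SASA (Å²), version 1
# computed as the central-residue SASA of an extended
# Gly-X-Gly tripeptide with the packaged radii (probe 1.4 Å,
# 960 Shrake-Rupley points/atom)
ALA	114.77
ARG	260.55
ASN	166.39
ASP	159.84
CYS	145.05
GLN	199.96
GLU	194.09
GLY	87.36
HIS	216.23
ILE	188.66
LEU	187.61
LYS	225.87
MET	214.43
PHE	252.88
PRO	172.15
SER	127.05
THR	151.63
TRP	305.92
TYR	261.44
VAL	162.68
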