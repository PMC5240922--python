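# Residue-type contact normalization N_i: maximum total heavy-atom
# contact count (4.5 A) per residue type over the packaged synthetic
# structure set (synthetic_multiatom_structure, seeds 0-4).
# Substitute published protein-structure-network values for real
# structures via load_contact_normalization(path).
# columns: residue<TAB>N
ALA	58.0
ARG	74.0
ASN	54.0
ASP	77.0
CYS	68.0
GLN	79.0
GLU	77.0
GLY	74.0
HIS	66.0
ILE	62.0
LEU	78.0
LYS	75.0
MET	63.0
PHE	62.0
PRO	72.0
SER	69.0
THR	73.0
TRP	73.0
TYR	67.0
VAL	60.0
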