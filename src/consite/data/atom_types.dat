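# PDB atom name -> parm94 atom type, for the 20 standard residues.
# columns: residue_name (or * for any)  atom_name  parm94_type
# Lookup order: (residue, name), then (*, name), then element-generic fallback.
# Backbone (any residue)
*    N    N
*    CA   CT
*    C    C
*    O    O
*    OXT  O2
*    H    H
*    H2   H
*    H3   H
*    HA   H1
# glycine has two alpha hydrogens
GLY  HA2  H1
GLY  HA3  H1
GLY  CA   CT
# N-terminal amine hydrogens fold to the amide type
*    H1   H
# --- side chains, heavy atoms ---
ALA  CB   CT
ARG  CB   CT
ARG  CG   CT
ARG  CD   CT
ARG  NE   N2
ARG  CZ   CA
ARG  NH1  N2
ARG  NH2  N2
ASN  CB   CT
ASN  CG   C
ASN  OD1  O
ASN  ND2  N
ASP  CB   CT
ASP  CG   C
ASP  OD1  O2
ASP  OD2  O2
CYS  CB   CT
CYS  SG   SH
GLN  CB   CT
GLN  CG   CT
GLN  CD   C
GLN  OE1  O
GLN  NE2  N
GLU  CB   CT
GLU  CG   CT
GLU  CD   C
GLU  OE1  O2
GLU  OE2  O2
HIS  CB   CT
HIS  CG   CC
HIS  ND1  NA
HIS  CD2  CV
HIS  CE1  CR
HIS  NE2  NB
ILE  CB   CT
ILE  CG1  CT
ILE  CG2  CT
ILE  CD1  CT
LEU  CB   CT
LEU  CG   CT
LEU  CD1  CT
LEU  CD2  CT
LYS  CB   CT
LYS  CG   CT
LYS  CD   CT
LYS  CE   CT
LYS  NZ   N3
MET  CB   CT
MET  CG   CT
MET  SD   S
MET  CE   CT
PHE  CB   CT
PHE  CG   CA
PHE  CD1  CA
PHE  CD2  CA
PHE  CE1  CA
PHE  CE2  CA
PHE  CZ   CA
PRO  CB   CT
PRO  CG   CT
PRO  CD   CT
SER  CB   CT
SER  OG   OH
THR  CB   CT
THR  OG1  OH
THR  CG2  CT
TRP  CB   CT
TRP  CG   C*
TRP  CD1  CW
TRP  CD2  CB
TRP  NE1  NA
TRP  CE2  CN
TRP  CE3  CA
TRP  CZ2  CA
TRP  CZ3  CA
TRP  CH2  CA
TYR  CB   CT
TYR  CG   CA
TYR  CD1  CA
TYR  CD2  CA
TYR  CE1  CA
TYR  CE2  CA
TYR  CZ   C
TYR  OH   OH
VAL  CB   CT
VAL  CG1  CT
VAL  CG2  CT
# --- common polar side-chain hydrogens ---
SER  HG   HO
THR  HG1  HO
TYR  HH   HO
CYS  HG   HS
LYS  HZ1  H
LYS  HZ2  H
LYS  HZ3  H
ARG  HE   H
ARG  HH11 H
ARG  HH12 H
ARG  HH21 H
ARG  HH22 H
ASN  HD21 H
ASN  HD22 H
GLN  HE21 H
GLN  HE22 H
HIS  HD1  H
HIS  HE2  H
TRP  HE1  H
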