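# tailsolv GB/SA parameter set (united heavy atoms)
# Hydrogen charges are collapsed onto their bonded heavy atoms; intrinsic
# radii are mbondi-style per-element values; screening factors are HCT-style.
# columns: residue  atom  charge(e)  intrinsic_radius(A)  screening_scale
ALA  N     -0.1500  1.55  0.79
ALA  CA     0.1000  1.70  0.72
ALA  C      0.6000  1.70  0.72
ALA  O     -0.5500  1.50  0.85
ALA  CB     0.0000  1.70  0.72
ARG  N     -0.1500  1.55  0.79
ARG  CA     0.1000  1.70  0.72
ARG  C      0.6000  1.70  0.72
ARG  O     -0.5500  1.50  0.85
ARG  CB     0.0000  1.70  0.72
ARG  CG     0.0000  1.70  0.72
ARG  CD     0.1000  1.70  0.72
ARG  NE     0.1000  1.55  0.79
ARG  CZ     0.4000  1.70  0.72
ARG  NH1    0.2000  1.55  0.79
ARG  NH2    0.2000  1.55  0.79
ASN  N     -0.1500  1.55  0.79
ASN  CA     0.1000  1.70  0.72
ASN  C      0.6000  1.70  0.72
ASN  O     -0.5500  1.50  0.85
ASN  CB     0.0000  1.70  0.72
ASN  CG     0.5500  1.70  0.72
ASN  OD1   -0.5500  1.50  0.85
ASN  ND2    0.0000  1.55  0.79
ASP  N     -0.1500  1.55  0.79
ASP  CA     0.1000  1.70  0.72
ASP  C      0.6000  1.70  0.72
ASP  O     -0.5500  1.50  0.85
ASP  CB    -0.1000  1.70  0.72
ASP  CG     0.3000  1.70  0.72
ASP  OD1   -0.6000  1.50  0.85
ASP  OD2   -0.6000  1.50  0.85
CYS  N     -0.1500  1.55  0.79
CYS  CA     0.1000  1.70  0.72
CYS  C      0.6000  1.70  0.72
CYS  O     -0.5500  1.50  0.85
CYS  CB     0.0900  1.70  0.72
CYS  SG    -0.0900  1.80  0.96
GLN  N     -0.1500  1.55  0.79
GLN  CA     0.1000  1.70  0.72
GLN  C      0.6000  1.70  0.72
GLN  O     -0.5500  1.50  0.85
GLN  CB     0.0000  1.70  0.72
GLN  CG     0.0000  1.70  0.72
GLN  CD     0.5500  1.70  0.72
GLN  OE1   -0.5500  1.50  0.85
GLN  NE2    0.0000  1.55  0.79
GLU  N     -0.1500  1.55  0.79
GLU  CA     0.1000  1.70  0.72
GLU  C      0.6000  1.70  0.72
GLU  O     -0.5500  1.50  0.85
GLU  CB     0.0000  1.70  0.72
GLU  CG    -0.1000  1.70  0.72
GLU  CD     0.3000  1.70  0.72
GLU  OE1   -0.6000  1.50  0.85
GLU  OE2   -0.6000  1.50  0.85
GLY  N     -0.1500  1.55  0.79
GLY  CA     0.1000  1.70  0.72
GLY  C      0.6000  1.70  0.72
GLY  O     -0.5500  1.50  0.85
HIS  N     -0.1500  1.55  0.79
HIS  CA     0.1000  1.70  0.72
HIS  C      0.6000  1.70  0.72
HIS  O     -0.5500  1.50  0.85
HIS  CB     0.0000  1.70  0.72
HIS  CG     0.1000  1.70  0.72
HIS  ND1   -0.1500  1.55  0.79
HIS  CD2    0.1000  1.70  0.72
HIS  CE1    0.2000  1.70  0.72
HIS  NE2   -0.2500  1.55  0.79
ILE  N     -0.1500  1.55  0.79
ILE  CA     0.1000  1.70  0.72
ILE  C      0.6000  1.70  0.72
ILE  O     -0.5500  1.50  0.85
ILE  CB     0.0000  1.70  0.72
ILE  CG1    0.0000  1.70  0.72
ILE  CG2    0.0000  1.70  0.72
ILE  CD1    0.0000  1.70  0.72
LEU  N     -0.1500  1.55  0.79
LEU  CA     0.1000  1.70  0.72
LEU  C      0.6000  1.70  0.72
LEU  O     -0.5500  1.50  0.85
LEU  CB     0.0000  1.70  0.72
LEU  CG     0.0000  1.70  0.72
LEU  CD1    0.0000  1.70  0.72
LEU  CD2    0.0000  1.70  0.72
LYS  N     -0.1500  1.55  0.79
LYS  CA     0.1000  1.70  0.72
LYS  C      0.6000  1.70  0.72
LYS  O     -0.5500  1.50  0.85
LYS  CB     0.0000  1.70  0.72
LYS  CG     0.0000  1.70  0.72
LYS  CD     0.0000  1.70  0.72
LYS  CE     0.2500  1.70  0.72
LYS  NZ     0.7500  1.55  0.79
MET  N     -0.1500  1.55  0.79
MET  CA     0.1000  1.70  0.72
MET  C      0.6000  1.70  0.72
MET  O     -0.5500  1.50  0.85
MET  CB     0.0000  1.70  0.72
MET  CG     0.0600  1.70  0.72
MET  SD    -0.1200  1.80  0.96
MET  CE     0.0600  1.70  0.72
PHE  N     -0.1500  1.55  0.79
PHE  CA     0.1000  1.70  0.72
PHE  C      0.6000  1.70  0.72
PHE  O     -0.5500  1.50  0.85
PHE  CB     0.0000  1.70  0.72
PHE  CG     0.0000  1.70  0.72
PHE  CD1    0.0000  1.70  0.72
PHE  CD2    0.0000  1.70  0.72
PHE  CE1    0.0000  1.70  0.72
PHE  CE2    0.0000  1.70  0.72
PHE  CZ     0.0000  1.70  0.72
PRO  N     -0.1500  1.55  0.79
PRO  CA     0.1000  1.70  0.72
PRO  C      0.6000  1.70  0.72
PRO  O     -0.5500  1.50  0.85
PRO  CB     0.0000  1.70  0.72
PRO  CG     0.0000  1.70  0.72
PRO  CD     0.0000  1.70  0.72
SER  N     -0.1500  1.55  0.79
SER  CA     0.1000  1.70  0.72
SER  C      0.6000  1.70  0.72
SER  O     -0.5500  1.50  0.85
SER  CB     0.2200  1.70  0.72
SER  OG    -0.2200  1.50  0.85
THR  N     -0.1500  1.55  0.79
THR  CA     0.1000  1.70  0.72
THR  C      0.6000  1.70  0.72
THR  O     -0.5500  1.50  0.85
THR  CB     0.2700  1.70  0.72
THR  OG1   -0.2700  1.50  0.85
THR  CG2    0.0000  1.70  0.72
TRP  N     -0.1500  1.55  0.79
TRP  CA     0.1000  1.70  0.72
TRP  C      0.6000  1.70  0.72
TRP  O     -0.5500  1.50  0.85
TRP  CB     0.0000  1.70  0.72
TRP  CG     0.0000  1.70  0.72
TRP  CD1    0.0600  1.70  0.72
TRP  CD2    0.0000  1.70  0.72
TRP  NE1   -0.0600  1.55  0.79
TRP  CE2    0.0000  1.70  0.72
TRP  CE3    0.0000  1.70  0.72
TRP  CZ2    0.0000  1.70  0.72
TRP  CZ3    0.0000  1.70  0.72
TRP  CH2    0.0000  1.70  0.72
TYR  N     -0.1500  1.55  0.79
TYR  CA     0.1000  1.70  0.72
TYR  C      0.6000  1.70  0.72
TYR  O     -0.5500  1.50  0.85
TYR  CB     0.0000  1.70  0.72
TYR  CG     0.0000  1.70  0.72
TYR  CD1    0.0000  1.70  0.72
TYR  CD2    0.0000  1.70  0.72
TYR  CE1    0.0000  1.70  0.72
TYR  CE2    0.0000  1.70  0.72
TYR  CZ     0.3300  1.70  0.72
TYR  OH    -0.3300  1.50  0.85
VAL  N     -0.1500  1.55  0.79
VAL  CA     0.1000  1.70  0.72
VAL  C      0.6000  1.70  0.72
VAL  O     -0.5500  1.50  0.85
VAL  CB     0.0000  1.70  0.72
VAL  CG1    0.0000  1.70  0.72
VAL  CG2    0.0000  1.70  0.72
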