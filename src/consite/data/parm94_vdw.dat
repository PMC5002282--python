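# parm94 nonbonded (6-12) parameters.
# columns: atom_type  R* (vdW radius, Angstrom)  epsilon (well depth, kcal/mol)
H    0.6000  0.0157
HO   0.0000  0.0000
HS   0.6000  0.0157
HC   1.4870  0.0157
H1   1.3870  0.0157
H2   1.2870  0.0157
H3   1.1870  0.0157
HP   1.1000  0.0157
HA   1.4590  0.0150
H4   1.4090  0.0150
H5   1.3590  0.0150
HW   0.0000  0.0000
O    1.6612  0.2100
O2   1.6612  0.2100
OW   1.7683  0.1520
OH   1.7210  0.2104
OS   1.6837  0.1700
C    1.9080  0.0860
CA   1.9080  0.0860
CB   1.9080  0.0860
CC   1.9080  0.0860
CK   1.9080  0.0860
CM   1.9080  0.0860
CN   1.9080  0.0860
CQ   1.9080  0.0860
CR   1.9080  0.0860
CV   1.9080  0.0860
CW   1.9080  0.0860
C*   1.9080  0.0860
CT   1.9080  0.1094
N    1.8240  0.1700
NA   1.8240  0.1700
NB   1.8240  0.1700
NC   1.8240  0.1700
N2   1.8240  0.1700
N3   1.8240  0.1700
N*   1.8240  0.1700
S    2.0000  0.2500
SH   2.0000  0.2500
P    2.1000  0.2000
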