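# Drug-like base structures for the synthetic compound-library generator.
# One SMILES per line; lines starting with '#' are comments. These are
# well-known small-molecule drugs and drug-like scaffolds spanning acids,
# bases, neutrals and zwitterions; the generator optionally decorates them
# (aryl halogenation, methylation) to extend library capacity.
CC(=O)Oc1ccccc1C(=O)O
CC(=O)Nc1ccc(O)cc1
CC(C)Cc1ccc(cc1)C(C)C(=O)O
Cn1cnc2c1c(=O)n(C)c(=O)n2C
CN1CCCC1c1cccnc1
CCOC(=O)c1ccc(N)cc1
CCN(CC)CC(=O)Nc1c(C)cccc1C
CCN(CC)CCOC(=O)c1ccc(N)cc1
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
CC(C)NCC(O)COc1cccc2ccccc12
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1
CN(C)CCCN1c2ccccc2CCc2ccccc21
CN(C)CCOC(c1ccccc1)c1ccccc1
COCCc1ccc(OCC(O)CNC(C)C)cc1
COc1ccc2cc(ccc2c1)C(C)C(=O)O
CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1
O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1
NC(=O)N1c2ccccc2C=Cc2ccccc21
CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1
CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21
OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1
CN(C)CCC=C1c2ccccc2CCc2ccccc21
CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
CN(C)CC1CCCCC1(O)c1cccc(OC)c1
O=S(=O)(Nc1cc(C)on1)c1ccc(N)cc1
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC
Cc1ncc([N+](=O)[O-])n1CCO
NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
Cn1c(=O)c2[nH]cnc2n(C)c1=O
COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC
CCOC(=O)C1=C(COCCN)NC(C)=C(C1c1ccccc1Cl)C(=O)OC
COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]
COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
N#CNC(=NC)NCCSCc1nc[nH]c1C
CNC(C)C(O)c1ccccc1
CC(N)Cc1ccccc1
CC(N)COc1c(C)cccc1C
CCCCC1C(=O)N(c2ccccc2)N(c2ccccc2)C1=O
CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1
COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl
Cc1cccc(Nc2ccccc2C(=O)O)c1C
Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F
OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O
OC1N=C(c2ccccc2)c2cc(Cl)ccc2NC1=O
Cc1nnc2CN=C(c3ccccc3)c3cc(Cl)ccc3-n12
CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O
CC(CS)C(=O)N1CCCC1C(=O)O
Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1
CCCN(CCC)S(=O)(=O)c1ccc(cc1)C(=O)O
CC(=O)Nc1nnc(s1)S(N)(=O)=O
NNC(=O)c1ccncc1
NC(=O)c1cnccn1
CCC(CO)NCCNC(CC)CO
CN(C)C(=N)NC(=N)N
OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21
CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21
OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F
Clc1ccccc1C(n1ccnc1)(c1ccccc1)c1ccccc1
Clc1ccc(C(Cn2ccnc2)OCc3ccc(Cl)cc3Cl)c(Cl)c1
CC(C)(C)C#CC=CCN(C)Cc1cccc2ccccc12
OC(=O)COCCN1CCN(CC1)C(c1ccccc1)c1ccc(Cl)cc1
CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1
CC(CN1c2ccccc2Sc2ccccc21)N(C)C
CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1
O=c1[nH]cc(F)c(=O)[nH]1
COc1ccc2[nH]cc(CCNC(C)=O)c2c1
NCCc1c[nH]c2ccc(O)cc12
NCCc1ccc(O)c(O)c1
CNCC(O)c1ccc(O)c(O)c1
NCC(CC(=O)O)c1ccc(Cl)cc1
NCC1(CC(=O)O)CCCCC1
CC(C)CC(CN)CC(=O)O
CCCC(CCC)C(=O)O
CCC1(c2ccccc2)C(=O)NC(=O)NC1=O
CCC1(c2ccccc2)C(=O)NCNC1=O
Nc1nnc(c(N)n1)-c1cccc(Cl)c1Cl
NC(Cc1ccc(O)c(O)c1)C(=O)O
CC(N)(Cc1ccc(O)c(O)c1)C(=O)O
CC1=CC(=O)N(c2ccccc2)N1C
OC(=O)c1ccccc1O
c1ccc(-c2ccccc2)cc1
CCOc1ccc(NC(C)=O)cc1
CC(=O)c1ccc(OC)cc1
COc1ccccc1OCCNCC(O)COc1cccc2[nH]c3ccccc3c12
CN1CCN(CC1)c1ccc(N)cc1
Oc1ccc(CCN2CCCC2)cc1
CC(C)Oc1ccccc1C(=O)O
CCOC(=O)c1cncn1C
Fc1ccc(cc1)C(=O)CCCN1CCC(=O)N(C1)c1ccccc1
COc1cc2c(cc1OC)CN(C)CC2
Cc1oc(nc1CCOc1ccc(CC2SC(=O)NC2=O)cc1)-c1ccccc1
CN(C)c1ccc(cc1)C(O)c1ccc(cc1)N(C)C
CCN1CCCC1CNC(=O)c1cc(S(=O)(=O)CC)ccc1OC
Oc1cccc2cccnc12
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O
COc1ccc(Cl)cc1C(=O)NCCc1ccc(cc1)S(=O)(=O)NC(=O)NC1CCCCC1
CN(C)CCCC1(OCc2cc(C#N)ccc21)c1ccc(F)cc1
CCOc1ccc2nc(sc2c1)S(N)(=O)=O
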