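DUSP2
CD22
FLNA
PAX8
ARHGEF12
AKAP9
DLL4
AIP
CDC14B
FOXO3
EGR4
MUTYH
SS18L1
PRKCG
HOOK3
TCEA1
UBE2C
FIGF
TOP1
DTX1
TNF
CCNE1
BAIAP2L1
CDKN1A
TFRC (CD71)
DLL3
SSBP2
TRAF3
PSIP1
43717SEPT9
SPTBN1
HIST1H2AC
TFDP1
TRAF5
BACH2
TNFRSF10D
SLC45A3
NACA
ASPH
ZBTB16
EPHA2
APOD
KAT2B
ETV5
FGF13
FLT3LG
NEURL1
TNFRSF17 (BCMA)
BCL7A
YTHDF2
KIF5B
IRS1
DGKZ
CENPU
STIL
XKR3
CCT6B
CD28
OLIG1
CCND2
GID4
STYK1
ATF3
FGF9
ZNF703
AKAP12
PTCRA
SMAD6
DNAJB1
SUZ12
TRIM33
CDK9
FLYWCH1
HIST1H2BC
MAPK1
RAC2
TCF7L2
USP42
FGFR1OP
MTCP1
PTPRO
SH3D19
CTDSP2
ID3
SMAP1
STL
TAL1
DNMT3A
IKBKE
IKZF3
AKT3
HSPA4
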