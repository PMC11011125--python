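ATIC
PLAG1
CD36
HSP90AB1
DNMT1
WDR1
CDC14A
MALT1
SP3
MAP3K14
TGFBI
BRSK1
KIT (CD117)
MSH6
HIST1H1D
HEY1
FOXO1
PRKCA
CCNB1IP1
FANCC
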