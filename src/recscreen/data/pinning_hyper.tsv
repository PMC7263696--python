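gene	recombinant_pct
CSM1	100
ELG1	100
MSH2	100
RAD27	100
RRM3	100
SGS1	100
TSA1	100
DST1	98
RNH202	98
RNH203	98
MLH1	96
NUP170	96
PMS1	96
ALE1	94
APN1	94
NFI1	94
YGR117C	94
YML020W	94
YMR166C	94
YOR072W	94
RPL23A	94
DIA2	92
EFT1	92
MDM1	92
MSN4	92
PNS1	92
RMI1	92
RRT14	92
SAC3	92
YDR230W	92
YLR235C	92
YNL122C	92
YTA7	92
FSH1	90
GET3	90
KGD2	90
MID2	90
POL32	90
RNH201	90
YGL159W	90
YJL043W	90
YLR279W	90
YOR082C	90
ARP8	88
BIO3	88
COX7	88
DCS2	88
DDC1	88
FUS2	88
HST3	88
KIP1	88
MFT1	88
MNT2	88
MRPL51	88
NIT3	88
PCL10	88
PET123	88
PHM8	88
REC114	88
RGS2	88
SCO1	88
SPR1	88
TOM5	88
ULS1	88
YDL009C	88
YEL020C	88
YGL042C	88
YJL017W	88
YJR018W	88
YJR124C	88
YKL091C	88
YKL162C	88
YNL179C	88
YOR309C	88
YOR333C	88
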