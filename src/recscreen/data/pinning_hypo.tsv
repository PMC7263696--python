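gene	recombinant_pct
YCL021W-A	0.0
YEL045C	0.0
GLY1	0.0
HIS5	0.0
RAD52	2.1
GCN4	2.9
CYS4	3.1
POS5	3.1
REC104	4.2
YHR080C	4.2
ATP15	4.8
YPR099C	4.9
YOR302W	5.3
ACO2	6.4
MDM20	6.4
MDM10	6.9
NPL3	7.1
HIS7	7.7
FUN12	8.3
BDF1	11.1
YNL011C	12.5
SWI6	12.8
URA1	13.2
YGR272C	13.2
BUD19	13.3
UGO1	13.3
YBL065W	14.6
SWI3	14.8
BRE4	15.2
YGR139W	15.6
PMD1	15.8
YHL041W	15.8
ERG28	16.7
SLX5	16.7
SIP3	17.2
BEM1	18.8
BUB3	18.8
OPI3	18.8
YER038W-A	18.9
ARG7	19.1
LIN1	19.6
OPY2	20.0
HEF3	20.0
DAL81	20.9
YLR361C-A	21.3
RPL22A	21.6
RSM7	21.7
CCR4	22.2
LOC1	22.2
AHC1	22.9
CIN1	22.9
VRP1	22.9
YEL014C	22.9
CDC40	23.1
MDM34	23.4
OST4	23.5
YOL013W-B	24.0
YCK1	24.3
KNH1	25.0
SHE4	25.0
SNF6	25.0
YDL187C	25.0
LRP1	25.7
ACM1	25.9
VCX1	26.7
BUB1	26.8
CCW12	27.1
HAM1	27.1
HST4	27.1
PHO85	27.1
PRM4	27.1
RIM1	27.1
UBP15	27.1
VMA21	27.1
YBR075W	27.1
AAT2	27.5
RAD50	27.8
ARG2	28.1
IRE1	28.2
PDR16	28.2
RNR1	28.2
YKR023W	28.6
ATP1	29.2
FIT2	29.2
HSP42	29.2
RAD54	29.2
RAD55	29.2
SNO1	29.2
SPE2	29.2
SPT21	29.2
TCD1	29.2
TPM1	29.2
YDR157W	29.2
YDR535C	29.2
YNL097C-A	29.2
YME1	29.6
NGG1	30.3
POP2	30.4
ATP11	30.8
RPL37B	31.0
HFI1	31.0
YML013C-A	31.1
AIM39	31.3
CIK1	31.3
HOL1	31.3
MET22	31.3
SWH1	31.3
RNR4	31.3
RPN4	31.3
RPS18B	31.3
TSL1	31.3
VPS60	31.3
VTH1	31.3
YKE2	31.3
YNR040W	31.3
NUP84	31.6
BOI1	31.7
URA2	31.7
RTC3	31.8
THP1	31.8
BUD20	32.1
RPS16A	32.6
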