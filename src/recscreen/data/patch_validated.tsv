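gene	mean_rate	sd	p_value
WT	1.14E-05	2.84E-06
TSA1	1.23E-04	3.64E-05	7.76E-05
VMA11	1.19E-04	7.62E-06	1.27E-08
RAD27	9.39E-05	2.59E-05	1.26E-04
RMI1	7.50E-05	6.85E-06	2.65E-07
TOP3	6.15E-05	3.80E-06	1.13E-07
SKN7	5.80E-05	6.85E-06	2.20E-06
APN1	5.75E-05	2.97E-05	3.79E-03
ELG1	5.09E-05	1.30E-05	1.73E-04
MLH1	4.86E-05	1.15E-05	3.43E-05
RNH203	4.68E-05	6.79E-06	1.31E-05
YLR235C	4.52E-05	2.57E-06	6.11E-07
TOF1	4.39E-05	1.40E-05	9.45E-04
YAP1	4.22E-05	5.04E-06	8.67E-06
RNH202	3.96E-05	1.38E-05	1.96E-03
RNH201	3.86E-05	6.08E-06	1.91E-06
SGS1	3.75E-05	1.42E-05	2.25E-03
YDL162C	3.34E-05	9.73E-06	1.38E-03
PMS1	3.33E-05	1.28E-05	3.46E-03
HYR1	3.16E-05	1.74E-05	1.85E-02
MGS1	3.10E-05	3.83E-06	6.14E-05
MSH2	3.09E-05	1.34E-06	1.55E-06
DST1	3.07E-05	6.56E-06	1.15E-04
YER188W	2.99E-05	1.27E-05	9.90E-03
CSM3	2.64E-05	3.65E-06	2.78E-04
HTA2	2.60E-05	6.24E-06	1.87E-03
RAD4	2.35E-05	2.46E-06	1.73E-03
MSH6	2.34E-05	1.02E-05	1.68E-02
RAD6	2.22E-05	7.25E-06	7.23E-03
RRM3	2.16E-05	8.30E-06	1.54E-02
CHL4	2.14E-05	5.86E-06	9.36E-03
THP2	1.94E-05	2.95E-06	2.52E-03
DFG16	1.80E-05	4.48E-06	2.44E-02
ABZ2	1.66E-05	3.93E-06	4.25E-02
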