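protein	uniprot	ratio	p_value
GRM2	Q14BI2	9.6	8.9E-02
CNTN1	P12960	9.5	4.3E-02
FN1	P11276	7.0	5.9E-02
KXD1	E9Q4P0	5.4	2.7E-02
SYP	Q62277	5.4	3.1E-02
EHD3	Q9QXY6	5.0	5.0E-03
GSTM3	P48774	5.0	7.8E-02
HSPA9	P38647	4.9	1.9E-05
RAB14	Q91V41	4.7	6.4E-02
CBR1	P48758	4.2	6.4E-02
KCNQ3	Q8K3F6	4.2	7.2E-02
NEFM	A0A0R4J036	4.2	3.3E-02
TF	Q921I1	4.0	7.9E-02
TPD52L2	Q9CYZ2	3.8	8.6E-02
ACO2	Q99KI0	3.3	4.2E-02
DPYSL5	Q9EQF6	2.6	8.0E-02
ATP5F1B	P56480	2.4	2.2E-02
SYT1	P46096	2.4	9.2E-02
CRMP1	Q6P1J1	2.4	3.7E-02
ATP5PO	Q9DB20	2.2	3.8E-02
RAB10	P61027	1.9	NA
HSPA8	P63017	1.8	9.6E-02
RAB3A	P63011	1.8	1.8E-02
AP2A1	P17426-2	1.8	1.3E-02
CFL1	P18760	1.7	9.1E-02
SUCLA2	Q9Z2I9	1.7	8.2E-02
PPP3CA	P63328	1.7	4.0E-02
SYNGR3	Q8R191	1.7	7.1E-02
GABRA5	Q8BHJ7	1.6	5.7E-02
PHB2	O35129	1.6	1.8E-02
YWHAG	P61982	1.6	1.6E-02
HSP90AA1	P07901	1.5	5.3E-02
PHB	P67778	1.5	7.8E-03
EIF3J	Q3UGC7	1.5	8.1E-02
SLC25A3	Q8VEM8	1.5	7.5E-02
ACTB	P60710	1.3	3.3E-02
YWHAE	P62259	NF-V	7.9E-04
VAMP2	P63044	NF-V	1.0E-02
INA	P46660	NF-V	1.6E-02
TMEFF2	Q9QYM9	NF-V	3.7E-02
RAB35	Q6PHN9	NF-V	4.1E-02
NEFH	P19246	NF-V	6.0E-02
UQCRC1	Q9CZ13	NF-V	6.3E-02
ATP5PB	Q9CQQ7	NF-V	1.2E-06
CCT6A	P80317	NF-V	2.8E-06
DDAH1	Q9CWS0	NF-V	2.8E-06
RPL18A	P62717	0.2	3.4E-02
GNB1	P62874	0.2	3.9E-02
ELAVL3	Q60900-2	0.2	4.2E-02
WDR7	Q920I9	0.2	5.8E-02
RPL10A	P53026	0.3	2.0E-02
RBMXL1	Q91VM5	0.3	3.4E-02
HNRNPA1	P49312	0.4	6.9E-02
HNRNPA3	Q8BG05	0.4	8.5E-02
TUBB6	Q922F4	0.4	7.9E-02
PSMC6	P62334	0.5	5.2E-02
CAMK2A	P11798	0.5	2.9E-04
EPB41L1	E9PV14	0.5	3.6E-02
CNP	P16330	0.7	6.8E-02
AP1B1	O35643	0.7	7.6E-02
TUBA1A	P68369	0.8	1.4E-02
PKM	P52480	0.8	8.0E-02
RPL27	P61358	NF-DZP	1.5E-02
ILF3	Q9Z1X4-3	NF-DZP	3.5E-02
ELAVL2	Q80UJ0	NF-DZP	5.5E-02
CCDC177	Q3UHB8	NF-DZP	2.8E-06
CDK5	P49615	NF-DZP	2.8E-06
RPL10	Q6ZWV3	NF-DZP	2.8E-06
UQCRQ	Q9CQ69	NF-DZP	2.8E-06
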