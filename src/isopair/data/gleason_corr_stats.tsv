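gene	event_type	effect	iso1_rho	iso1_fdr	iso2_rho	iso2_fdr	psi_rho	psi_fdr	printed_call
LIG4	Alternative promoter	Induction of promoter 2	-0.07	1.92E-01	0.09	1.07E-01	-0.18	4.21E-04	Consistent -
TACC2	Alternative promoter	Repression of promoter 1	-0.08	1.55E-01	0.01	9.26E-01	-0.08	1.88E-01	Inconclusive
TPD52	Alternative promoter	Induction of promoter 2	0.00	9.51E-01	0.02	7.73E-01	0.00	9.46E-01	Inconclusive
NUP93	Alternative promoter	Induction of promoter 1	-0.18	7.92E-04	-0.07	1.81E-01	0.04	4.75E-01	Opposite
RLN1	Alternative promoter	Repression of promoter 2	-0.16	1.98E-03					Not assessed
AP2S1	Alternative promoter	Induction of promoter 2	-0.01	8.72E-01					Not assessed
RLN2	Alternative promoter	Induction of promoter 1	-0.10	6.03E-02					Not assessed
PIK3R1	Alternative promoter	Repression of promoter 2	-0.07	2.51E-01	0.09	1.20E-01	-0.17	1.29E-03	Inconclusive
MAPRE2	Alternative promoter	Switch to promoter 2	-0.07	1.92E-01	-0.06	2.73E-01	0.06	3.23E-01	Inconclusive
NDUFAF4	Alternative promoter	Repression of promoter 2	0.00	9.79E-01					Not assessed
DCXR	Alternative promoter	Repression of promoter 2	-0.29	4.07E-09					Not assessed
PEX10	Alternative promoter	Switch to promoter 2	0.08	1.50E-01					Not assessed
SNAPC2	Alternative promoter	Switch to promoter 2	0.15	5.48E-03	-0.18	3.55E-04	0.21	5.13E-05	Opposite
ATP6V0D1	Alternative promoter	Repression of promoter 2	-0.11	3.43E-02					Not assessed
ARRDC1	Alternative promoter	Induction of promoter 2	0.12	2.00E-02					Not assessed
DENND1A	Alternative promoter	Repression of promoter 2	-0.02	8.10E-01					Not assessed
KLHL36	Alternative promoter	Induction of promoter 2	-0.13	1.67E-02					Not assessed
RAB3IL1	Alternative promoter	Repression of promoter 2	0.06	3.17E-01	0.32	9.13E-12	-0.02	7.15E-01	Opposite
ACER3	Alternative promoter	Repression of promoter 2	0.16	3.79E-03					Not assessed
OSBPL1A	Alternative promoter	Induction of promoter 2	0.05	4.00E-01	0.13	1.58E-02	-0.07	2.33E-01	Consistent
TRIM16	Alternative promoter	Induction of promoter 2	0.10	6.06E-02					Not assessed
VSIG10L	Alternative promoter	Induction of promoter 1	-0.16	1.98E-03					Not assessed
SEPT5	Alternative promoter	Repression of promoter 2	0.17	1.12E-03	0.12	1.93E-02	-0.04	4.91E-01	Opposite
HMGCR	Alternative promoter	Repression of promoter 1	0.03	6.56E-01	-0.05	4.54E-01	0.07	2.33E-01	Inconclusive
RDH13	Alternative promoter	Induction of promoter 1	0.03	7.01E-01	0.08	1.20E-01	-0.10	1.00E-01	Inconclusive
GPRIN2	Alternative promoter	Repression of promoter 2			-0.01	8.93E-01			Not assessed
CLK3	Alternative promoter	Repression of promoter 1	-0.13	1.58E-02	-0.05	3.98E-01	0.07	2.33E-01	Consistent
RNH1	Alternative promoter	Induction of promoter 1	0.05	4.41E-01	0.07	1.83E-01	-0.01	9.23E-01	Inconclusive
ZFAND6	Alternative promoter	Repression of promoter 2	0.07	1.87E-01	0.05	3.82E-01	-0.03	6.36E-01	Inconclusive
CDIP1	Alternative promoter	Repression of promoter 2	0.02	8.10E-01	0.03	6.81E-01	-0.01	9.23E-01	Inconclusive
YIF1B	Alternative promoter	Switch to promoter 2	0.02	8.10E-01	-0.04	5.42E-01	0.05	4.39E-01	Inconclusive
LIMK2	Alternative promoter	Switch to promoter 2	-0.02	8.10E-01	-0.03	6.30E-01	0.00	9.49E-01	Inconclusive
TSC22D3	Alternative promoter	Repression of promoter 1	-0.15	5.15E-03	-0.01	9.26E-01	-0.09	1.14E-01	Consistent
ALDH1A3	Alternative promoter	Repression of promoter 1	-0.12	2.00E-02					Not assessed
TRABD	Alternative promoter	Switch to promoter 2	0.14	8.04E-03	-0.04	5.43E-01	0.05	4.39E-01	Inconclusive
LIMCH1	Alternative promoter	Repression of promoter 2	0.05	4.34E-01					Not assessed
GMFB	Alternative promoter	Induction of promoter 2	0.08	1.55E-01					Not assessed
MLST8	Alternative promoter	Switch to promoter 1	0.19	5.32E-04	0.19	2.05E-04	0.07	2.14E-01	Inconclusive
TLE3	Alternative promoter	Induction of promoter 2	0.05	4.28E-01	-0.10	7.19E-02	0.07	2.33E-01	Inconclusive
UBA1	Alternative promoter	Repression of promoter 1	0.09	8.99E-02	0.03	5.95E-01	0.01	8.68E-01	Inconclusive
TNRC6B	Alternative promoter	Repression of promoter 2	-0.05	4.00E-01	-0.09	1.19E-01	0.09	1.11E-01	Inconclusive
FDFT1	Alternative promoter	Repression of promoter 2	-0.02	7.41E-01	0.07	2.07E-01	-0.07	2.14E-01	Inconclusive
GREB1	Alternative promoter	Induction of promoter 2	-0.05	4.41E-01	-0.14	5.45E-03	0.04	4.60E-01	Opposite
NCAPD3	Alternative promoter	Induction of promoter 2	-0.23	3.61E-06					Not assessed
SLC36A4	Alternative promoter	Induction of promoter 2	0.12	1.88E-02					Not assessed
KLC2	Alternative promoter	Repression of promoter 1	-0.02	8.10E-01	0.13	1.58E-02	-0.04	4.60E-01	Inconclusive
RAP1GAP	Alternative promoter	Repression of promoter 1	0.01	8.79E-01					Not assessed
TMEM79	Alternative promoter	Repression of promoter 1	-0.04	4.70E-01	0.15	3.46E-03	-0.09	1.11E-01	Inconclusive
NR4A1	Alternative promoter	Induction of promoter 2	0.10	5.44E-02	0.00	9.79E-01	0.10	7.40E-02	Inconclusive
ZNF32	Alternative promoter	Repression of promoter 2	-0.22	1.32E-05	-0.22	1.11E-05	-0.09	1.31E-01	Consistent -
C1QTNF3	Alternative promoter	Induction of promoter 1	0.08	1.58E-01					Not assessed
UBE2D3	Alternative promoter	Switch to promoter 2	0.18	7.24E-04	0.08	1.27E-01	-0.02	7.15E-01	Inconclusive
KRT8	Alternative promoter	Repression of promoter 1	-0.05	3.81E-01	-0.16	2.07E-03	0.01	8.68E-01	Inconclusive
ELOVL1	Alternative promoter	Induction of promoter 2	0.18	7.24E-04					Not assessed
RCAN1	Alternative promoter	Induction of promoter 2	0.10	5.13E-02	-0.01	8.70E-01	0.12	3.69E-02	Inconclusive
SORBS3	Alternative promoter	Induction of promoter 2	0.12	2.21E-02					Not assessed
MAT2A	Alternative 3' end	Repression of isoform 2	0.04	5.39E-01	0.27	3.68E-08	-0.33	8.82E-13	Opposite
CNNM2	Alternative 3' end	Induction of isoform 1	-0.06	3.30E-01	0.03	5.87E-01	-0.08	2.04E-01	Inconclusive
TMEM125	Alternative 3' end	Induction of isoform 1			-0.19	2.05E-04			Not assessed
CBWD2	Alternative 3' end	Induction of isoform 2	0.13	1.37E-02					Not assessed
NDUFV3	Alternative exon	Switch to isoform 2 (exon excluded)	0.14	8.04E-03	-0.07	2.48E-01	0.13	2.23E-02	Opposite
ZNF678	Alternative exon	Switch to isoform 2 (exon excluded)	-0.07	1.87E-01					Not assessed
ZNF121	Alternative exon	Switch to isoform 2 (exon excluded)	-0.13	1.63E-02	0.08	1.20E-01	-0.14	1.27E-02	Consistent
SPATC1L	Alternative exon	Induction of isoform 2 (exon included)	-0.13	1.58E-02					Not assessed
MOCOS	Alternative exon	Switch to isoform 2 (exon excluded)	-0.01	8.72E-01					Not assessed
RBM45	Alternative exon	Switch to isoform 2 (exon included)	0.12	2.45E-02					Not assessed
MIPEP	Alternative exon	Repression of isoform 2 (exon excluded)	-0.14	9.92E-03					Not assessed
BBS4	Alternative exon	Induction of isoform 2 (exon included)	-0.08	1.87E-01					Not assessed
FAM195A	Alternative exon	Switch to isoform 1 (exon exluded)	0.04	5.43E-01	0.14	5.35E-03	-0.18	4.65E-04	Opposite
LINC01133	Alternative exon	Induction of isoform 1 (exon excluded)			-0.02	7.51E-01			Not assessed
SS18	Alternative exon	Switch to isoform 2 (exon excluded)	0.04	4.86E-01	-0.06	2.51E-01	0.07	2.33E-01	Inconclusive
RHOC	Alternative exon	Switch to isoform 2 (exon excluded)	0.29	4.07E-09	0.15	4.24E-03	0.21	3.63E-05	Opposite
ZNF226	Retained intron	Switch to isoform 1 (intron included)	0.01	8.67E-01	-0.10	7.49E-02	0.11	6.74E-02	Inconclusive
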