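gene	event_type	effect	iso1_rho	iso1_fdr	iso2_rho	iso2_fdr	psi_rho	psi_fdr	printed_call
LIG4	Alternative promoter	Induction of promoter 2	-0.04	6.05E-01	0.02	6.82E-01	-0.09	1.82E-01	Inconclusive
TACC2	Alternative promoter	Repression of promoter 1	-0.08	1.74E-01	-0.05	4.47E-01	-0.04	5.65E-01	Inconclusive
TPD52	Alternative promoter	Induction of promoter 2	-0.02	7.85E-01	-0.02	6.82E-01	-0.02	7.95E-01	Inconclusive
NUP93	Alternative promoter	Induction of promoter 1	-0.12	3.95E-02	0.03	6.65E-01	-0.05	4.43E-01	Opposite
RLN1	Alternative promoter	Repression of promoter 2	-0.22	1.82E-05					Not assessed
AP2S1	Alternative promoter	Induction of promoter 2	-0.04	5.51E-01					Not assessed
RLN2	Alternative promoter	Induction of promoter 1	-0.16	5.68E-03					Not assessed
PIK3R1	Alternative promoter	Repression of promoter 2	-0.02	7.92E-01	0.11	5.92E-02	-0.14	3.27E-02	Opposite -
MAPRE2	Alternative promoter	Switch to promoter 2	-0.02	7.56E-01	-0.02	6.82E-01	0.03	1.00E+00	Inconclusive
NDUFAF4	Alternative promoter	Repression of promoter 2	0.08	1.89E-01					Not assessed
DCXR	Alternative promoter	Repression of promoter 2	-0.30	6.32E-10					Not assessed
PEX10	Alternative promoter	Switch to promoter 2	0.10	9.95E-02					Not assessed
SNAPC2	Alternative promoter	Switch to promoter 2	0.13	2.87E-02	-0.23	5.57E-06	0.20	2.40E-04	Opposite
ATP6V0D1	Alternative promoter	Repression of promoter 2	-0.11	5.43E-02					Not assessed
ARRDC1	Alternative promoter	Induction of promoter 2	0.08	2.06E-01					Not assessed
DENND1A	Alternative promoter	Repression of promoter 2	-0.01	8.49E-01					Not assessed
KLHL36	Alternative promoter	Induction of promoter 2	-0.10	1.04E-01					Not assessed
RAB3IL1	Alternative promoter	Repression of promoter 2	0.08	1.71E-01	0.33	4.58E-12	0.00	9.75E-01	Opposite
ACER3	Alternative promoter	Repression of promoter 2	0.16	4.77E-03					Not assessed
OSBPL1A	Alternative promoter	Induction of promoter 2	0.04	5.38E-01	0.13	1.59E-02	-0.07	2.88E-01	Consistent
TRIM16	Alternative promoter	Induction of promoter 2	0.06	3.95E-01					Not assessed
VSIG10L	Alternative promoter	Induction of promoter 1	-0.12	5.43E-02					Not assessed
SEPT5	Alternative promoter	Repression of promoter 2	0.11	7.96E-02	0.07	2.54E-01	-0.01	8.89E-01	Inconclusive
HMGCR	Alternative promoter	Repression of promoter 1	0.00	9.91E-01	-0.04	5.77E-01	0.04	6.25E-01	Inconclusive
RDH13	Alternative promoter	Induction of promoter 1	-0.03	7.33E-01	0.10	7.19E-02	-0.12	9.32E-02	Inconclusive
GPRIN2	Alternative promoter	Repression of promoter 2			0.03	6.48E-01			Not assessed
CLK3	Alternative promoter	Repression of promoter 1	-0.15	6.05E-03	0.02	7.76E-01	0.02	8.63E-01	Consistent
RNH1	Alternative promoter	Induction of promoter 1	-0.02	7.92E-01	0.10	6.12E-02	-0.08	2.28E-01	Inconclusive
ZFAND6	Alternative promoter	Repression of promoter 2	0.03	6.50E-01	0.04	5.78E-01	-0.04	6.05E-01	Inconclusive
CDIP1	Alternative promoter	Repression of promoter 2	0.10	1.04E-01	0.02	7.82E-01	0.06	3.78E-01	Inconclusive
YIF1B	Alternative promoter	Switch to promoter 2	-0.01	8.87E-01	-0.10	6.71E-02	0.06	3.97E-01	Inconclusive
LIMK2	Alternative promoter	Switch to promoter 2	0.00	9.67E-01	-0.05	4.72E-01	0.00	9.75E-01	Inconclusive
TSC22D3	Alternative promoter	Repression of promoter 1	-0.13	3.44E-02	-0.07	2.54E-01	-0.03	6.59E-01	Consistent
ALDH1A3	Alternative promoter	Repression of promoter 1	-0.18	7.69E-04					Not assessed
TRABD	Alternative promoter	Switch to promoter 2	0.06	3.95E-01	-0.03	6.48E-01	0.03	7.83E-01	Inconclusive
LIMCH1	Alternative promoter	Repression of promoter 2	0.02	7.85E-01					Not assessed
GMFB	Alternative promoter	Induction of promoter 2	0.07	2.57E-01					Not assessed
MLST8	Alternative promoter	Switch to promoter 1	0.10	8.19E-02	0.15	6.14E-03	0.02	7.83E-01	Inconclusive
TLE3	Alternative promoter	Induction of promoter 2	0.03	6.38E-01	-0.11	3.84E-02	0.04	5.65E-01	Opposite
UBA1	Alternative promoter	Repression of promoter 1	0.12	5.43E-02	0.00	9.72E-01	0.06	3.99E-01	Inconclusive
TNRC6B	Alternative promoter	Repression of promoter 2	-0.04	6.31E-01	-0.03	6.48E-01	0.02	7.83E-01	Inconclusive
FDFT1	Alternative promoter	Repression of promoter 2	-0.05	4.82E-01	0.04	5.46E-01	-0.08	2.28E-01	Inconclusive
GREB1	Alternative promoter	Induction of promoter 2	-0.11	7.48E-02	-0.18	7.01E-04	0.01	8.96E-01	Opposite
NCAPD3	Alternative promoter	Induction of promoter 2	-0.23	1.82E-05					Not assessed
SLC36A4	Alternative promoter	Induction of promoter 2	0.07	2.59E-01					Not assessed
KLC2	Alternative promoter	Repression of promoter 1	-0.03	6.33E-01	0.13	1.81E-02	-0.08	2.78E-01	Inconclusive
RAP1GAP	Alternative promoter	Repression of promoter 1	0.02	7.85E-01					Not assessed
TMEM79	Alternative promoter	Repression of promoter 1	-0.08	1.71E-01	0.16	1.97E-03	-0.10	1.20E-01	Inconclusive
NR4A1	Alternative promoter	Induction of promoter 2	0.01	8.49E-01	-0.06	3.69E-01	0.08	2.62E-01	Inconclusive
ZNF32	Alternative promoter	Repression of promoter 2	-0.15	6.70E-03	0.02	7.34E-01	-0.08	2.33E-01	Inconclusive
C1QTNF3	Alternative promoter	Induction of promoter 1	0.03	6.74E-01					Not assessed
UBE2D3	Alternative promoter	Switch to promoter 2	0.20	2.96E-04	0.07	2.17E-01	-0.02	7.83E-01	Inconclusive
KRT8	Alternative promoter	Repression of promoter 1	-0.04	6.05E-01	-0.24	2.72E-06	0.04	6.05E-01	Inconclusive
ELOVL1	Alternative promoter	Induction of promoter 2	0.13	2.87E-02					Not assessed
RCAN1	Alternative promoter	Induction of promoter 2	0.09	1.26E-01	-0.01	8.69E-01	0.10	1.20E-01	Inconclusive
SORBS3	Alternative promoter	Induction of promoter 2	0.11	7.96E-02					Not assessed
MAT2A	Alternative 3' end	Repression of isoform 2	0.01	9.35E-01	0.18	7.83E-04	-0.21	8.42E-05	Opposite
CNNM2	Alternative 3' end	Induction of isoform 1	0.05	3.95E-01	0.05	4.47E-01	-0.04	6.05E-01	Inconclusive
TMEM125	Alternative 3' end	Induction of isoform 1			-0.16	2.80E-03			Not assessed
CBWD2	Alternative 3' end	Induction of isoform 2	0.08	1.74E-01					Not assessed
NDUFV3	Alternative exon	Switch to isoform 2 (exon excluded)	0.11	7.48E-02	-0.05	4.72E-01	0.11	1.00E-01	Inconclusive
ZNF678	Alternative exon	Switch to isoform 2 (exon excluded)	-0.02	7.43E-01					Not assessed
ZNF121	Alternative exon	Switch to isoform 2 (exon excluded)	-0.08	1.80E-01	0.03	6.48E-01	-0.09	1.82E-01	Inconclusive
SPATC1L	Alternative exon	Induction of isoform 2 (exon included)	-0.10	9.95E-02					Not assessed
MOCOS	Alternative exon	Switch to isoform 2 (exon excluded)	0.03	6.33E-01					Not assessed
RBM45	Alternative exon	Switch to isoform 2 (exon included)	0.08	1.71E-01					Not assessed
MIPEP	Alternative exon	Repression of isoform 2 (exon excluded)	-0.16	4.48E-03					Not assessed
BBS4	Alternative exon	Induction of isoform 2 (exon included)	-0.06	3.85E-01					Not assessed
FAM195A	Alternative exon	Switch to isoform 1 (exon exluded)	0.06	3.37E-01	0.10	6.85E-02	-0.10	1.20E-01	Inconclusive
LINC01133	Alternative exon	Induction of isoform 1 (exon excluded)			0.00	9.72E-01			Not assessed
SS18	Alternative exon	Switch to isoform 2 (exon excluded)	0.04	5.68E-01	-0.04	5.46E-01	0.06	3.97E-01	Inconclusive
RHOC	Alternative exon	Switch to isoform 2 (exon excluded)	0.15	6.05E-03	0.11	3.84E-02	0.11	1.00E-01	Inconclusive
ZNF226	Retained intron	Switch to isoform 1 (intron included)	-0.03	6.64E-01	-0.09	1.23E-01	0.07	3.35E-01	Inconclusive
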