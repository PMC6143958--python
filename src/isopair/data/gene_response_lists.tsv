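gene	experiment	category
RLN2	lncap	nochange
DENND1A	lncap	nochange
RAB3IL1	lncap	nochange
OSBPL1A	lncap	nochange
TRIM16	lncap	nochange
Sep-05	lncap	nochange
RDH13	lncap	nochange
ZFAND6	lncap	nochange
CDIP1	lncap	nochange
LIMK2	lncap	nochange
TSC22D3	lncap	nochange
GMFB	lncap	nochange
MLST8	lncap	nochange
znf32	lncap	nochange
C1QTNF3	lncap	nochange
UBE2D3	lncap	nochange
MAT2A	lncap	nochange
CBWD2	lncap	nochange
ZNF678	lncap	nochange
MOCOS	lncap	nochange
LIG4	lncap	up
TACC2	lncap	up
RLN1	lncap	up
AP2S1	lncap	up
DCXR	lncap	up
PEX10	lncap	up
SNAPC2	lncap	up
ATP6V0D1	lncap	up
ARRDC1	lncap	up
KLHL36	lncap	up
VSIG10L	lncap	up
HMGCR	lncap	up
CLK3	lncap	up
RNH1	lncap	up
YIF1B	lncap	up
PAK1IP1	lncap	up
ALDH1A3	lncap	up
TRABD	lncap	up
LIMCH1	lncap	up
UBA1	lncap	up
FDFT1	lncap	up
GREB1	lncap	up
NCAPD3	lncap	up
SLC36A4	lncap	up
KLC2	lncap	up
RAP1GAP	lncap	up
TMEM79	lncap	up
NR4A1	lncap	up
KRT8	lncap	up
ELOVL1	lncap	up
RCAN1	lncap	up
CNNM2	lncap	up
TMEM125	lncap	up
NDUFV3	lncap	up
SPATC1L	lncap	up
RBM45	lncap	up
MIPEP	lncap	up
BBS4	lncap	up
FAM195A	lncap	up
SS18	lncap	up
RHOC	lncap	up
ZNF226	lncap	up
TPD52	lncap	up
NUP93	lncap	down
PIK3R1	lncap	down
MAPRE2	lncap	down
NDUFAF4	lncap	down
ACER3	lncap	down
GPRIN2	lncap	down
TLE3	lncap	down
TNRC6B	lncap	down
SORBS3	lncap	down
ZNF121	lncap	down
LINC01133	lncap	down
LIG4	reciprocal	nochange
TACC2	reciprocal	nochange
NUP93	reciprocal	nochange
RLN1	reciprocal	nochange
RLN2	reciprocal	nochange
PIK3R1	reciprocal	nochange
MAPRE2	reciprocal	nochange
NDUFAF4	reciprocal	nochange
SNAPC2	reciprocal	nochange
ATP6V0D1	reciprocal	nochange
ARRDC1	reciprocal	nochange
DENND1A	reciprocal	nochange
KLHL36	reciprocal	nochange
RAB3IL1	reciprocal	nochange
ACER3	reciprocal	nochange
OSBPL1A	reciprocal	nochange
TRIM16	reciprocal	nochange
VSIG10L	reciprocal	nochange
SEPT5	reciprocal	nochange
RDH13	reciprocal	nochange
GPRIN2	reciprocal	nochange
CLK3	reciprocal	nochange
RNH1	reciprocal	nochange
ZFAND6	reciprocal	nochange
CDIP1	reciprocal	nochange
YIF1B	reciprocal	nochange
LIMK2	reciprocal	nochange
TSC22D3	reciprocal	nochange
TRABD	reciprocal	nochange
LIMCH1	reciprocal	nochange
GMFB	reciprocal	nochange
MLST8	reciprocal	nochange
TLE3	reciprocal	nochange
UBA1	reciprocal	nochange
TNRC6B	reciprocal	nochange
SLC36A4	reciprocal	nochange
KLC2	reciprocal	nochange
NR4A1	reciprocal	nochange
znf32	reciprocal	nochange
C1QTNF3	reciprocal	nochange
UBE2D3	reciprocal	nochange
RCAN1	reciprocal	nochange
SORBS3	reciprocal	nochange
MAT2A	reciprocal	nochange
CNNM2	reciprocal	nochange
CBWD2	reciprocal	nochange
NDUFV3	reciprocal	nochange
ZNF678	reciprocal	nochange
ZNF121	reciprocal	nochange
SPATC1L	reciprocal	nochange
MOCOS	reciprocal	nochange
RBM45	reciprocal	nochange
MIPEP	reciprocal	nochange
BBS4	reciprocal	nochange
FAM195A	reciprocal	nochange
LINC01133	reciprocal	nochange
SS18	reciprocal	nochange
RHOC	reciprocal	nochange
ICAM3	reciprocal	nochange
ZNF226	reciprocal	nochange
TPD52	reciprocal	up
AP2S1	reciprocal	up
DCXR	reciprocal	up
PEX10	reciprocal	up
HMGCR	reciprocal	up
ALDH1A3	reciprocal	up
FDFT1	reciprocal	up
GREB1	reciprocal	up
NCAPD3	reciprocal	up
RAP1GAP	reciprocal	up
TMEM79	reciprocal	up
KRT8	reciprocal	up
ELOVL1	reciprocal	up
TMEM125	reciprocal	up
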