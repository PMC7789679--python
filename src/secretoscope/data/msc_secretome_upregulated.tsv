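gene_id	protein_id	conditions
CHAD	O15335	healthy;traumatic;degenerative
CILP	O75339	healthy;traumatic;degenerative
FGA	P02671	healthy;traumatic;degenerative
FGB	P02675	healthy;traumatic;degenerative
DCN	P07585	healthy;traumatic;degenerative
CTSB	P07858	healthy;traumatic;degenerative
VCAN	P13611	healthy;traumatic;degenerative
ACAN	P16112	healthy;traumatic;degenerative
LAMA1	P25391	healthy;traumatic;degenerative
COMP	P49747	healthy;traumatic;degenerative
PRG4	Q92954	healthy;traumatic;degenerative
IGHA1	P01876	healthy;degenerative;IL1b
ABI3BP	Q7Z7G0	healthy;degenerative;IL1b
STC2	O76061	traumatic;degenerative;IL1b
SERPINA1	P01009	traumatic;degenerative;IL1b
MMP1	P03956	traumatic;degenerative;IL1b
SRGN	P10124	traumatic;degenerative;IL1b
MAN1A1	P33908	traumatic;degenerative;IL1b
CXCL12	P48061	traumatic;degenerative;IL1b
B2M	P61769	traumatic;degenerative;IL1b
FNDC1	Q4ZHG4	traumatic;degenerative;IL1b
SRPX2	O60687	traumatic;degenerative
SEMA7A	O75326	traumatic;degenerative
TIMP1	P01033	traumatic;degenerative
FGG	P02679	traumatic;degenerative
ALB	P02768	traumatic;degenerative
SERPINE2	P07093	traumatic;degenerative
CLU	P10909	traumatic;degenerative
CDH2	P19022	traumatic;degenerative
LUM	P51884	traumatic;degenerative
SRPX	P78539	traumatic;degenerative
COL7A1	Q02388	traumatic;degenerative
SPOCK1	Q08629	traumatic;degenerative
LTBP1	Q14766	traumatic;degenerative
TGFBI	Q15582	traumatic;degenerative
SBSN	Q6UWP8	traumatic;degenerative
FAM3C	Q92520	traumatic;degenerative
PXDN	Q92626	traumatic;degenerative
HTRA1	Q92743	traumatic;degenerative
CTHRC1	Q96CG8	traumatic;degenerative
HAPLN1	P10915	healthy
BPIFB1	Q8TDL5	healthy
APOA1	P02647	healthy
COL4A1	P02462	healthy
COL11A1	P12107	healthy
MUC5B	Q9HC84	healthy
IGKC	P01834	healthy
APOD	P05090	healthy
IGHG1	P01857	healthy
APCS	P02743	healthy
IGLL5	B9A064	healthy
ADAMTS2	O95450	healthy
ULBP2	Q9BZM5	healthy
OGN	P20774	healthy
EFEMP1	Q12805	healthy
IGFBP6	P24592	healthy
OLFML3	Q9NRN5	healthy
A2M	P01023	healthy
LOXL2	Q9Y4K0	healthy
NEGR1	Q7Z3B1	healthy
SDF4	Q9BRK5	healthy
BMP1	P13497	healthy
CST3	P01034	healthy
MMP14	P50281	healthy
FBN1	P35555	traumatic
GALNT1	Q10472	traumatic
CCDC80	Q76M96	traumatic
LTBP2	Q14767	traumatic
HPX	P02790	degenerative
ITIH1	P19827	degenerative
LGALS7;LGALS7B	P47929	degenerative
CLSTN1	O94985	degenerative
SMOC1	Q9H4F8	degenerative
ENO3	P13929	degenerative
VASN	Q6EMK4	degenerative
KRT16	P08779	degenerative
CFB	P00751	IL1b
IL6	P05231	IL1b
C3	P01024	IL1b
MMP10	P09238	IL1b
MYH7	P12883	IL1b
ALDH1A1	P00352	IL1b
LBP	P18428	IL1b
FABP1	P07148	IL1b
CHI3L1	P36222	IL1b
VCAM1	P19320	IL1b
CHI3L2	Q15782	IL1b
TNC	P24821	IL1b
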