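name	synonyms	is_pdz	n_pdz_domains	other_domains
AFAD	MLLT4,AF-6,AFADIN,I-AFADIN,S-AFADIN	1	1	DIL:1,FHA:1,RA:2
CSKP	CASK,CAGH39,CAMGUK,CMG,LIN-2,MICPCH,PALS3,TNRC8	1	1	GuKc:1,L27:2,S_TKc:1,SH3:1
DLG1	DLGH1,SAP97,SAP-97,HDLG	1	3	GuKc:1,L27:1,MAGUK_N_PEST:1,SH3:1
GORS2	GORASP2,GOLPH2,GOLPH6,GRASP55,GRS2,P59	1	1	
HTRA1	ARMD7,CARASIL,HTRA,L56,PRSS11	1	1	IB:1,KAZAL:1
INADL	CIPP,HINADL,INAD-LIKE,PATJ	1	10	L27:1
LIN7A	LIN7,MALS-1,VELI1,TIP-33	1	1	L27:1
LIN7C	MALS-3,VELI	1	1	L27:1
LNX1	LNX,PDZRN2	1	4	RING:1
LNX2	PDZRN1	1	4	RING:1
MAGI1	AIP-3,BAIAP1,BAP-1,TNRC19,WWP3	1	6	GuKc:1,WW:2
MAGI3	SLIPR	1	6	GuKc:1,WW:2
MPDZ	INAD,MUPP1	1	13	L27:1
MPP2	DLG2,PALS4	1	1	GuKc:1,L27:2,SH3:1
MPP5	PALS1	1	1	GuKc:1,L27:2,SH3:1
MPP6	FIN15,PALS2,VAM-1	1	1	GuKc:1,L27:2,SH3:1
MPP7	GM955	1	1	GuKc:1,L27:2,SH3:1
PTN13	FAP-1,PTP1E,PTP-BAS,PTP-BL,PTPL1,PTPLE	1	5	B41:1,FERM_C:1,KIND:1,PTPc:1
SCRIB	CRC,CRIB1,SCRB1,SCRIB1,VARTUL	1	4	LRR:11
SDCB1	MDA-9,ST1,SYNTENIN-1,TACIP18,SYCL,SDCBP	1	2	
SNTA1	SNT1,TACIP1,ALPHA-1-SYNTROPHIN	1	1	PH:1
SNTB1	59-DAP,A1B,BSYN2,SNT2,SNT2B1,TIP-43	1	1	PH:1
SNTB2	SNT3,SNT2B2,SNTL	1	1	PH:1
SNX27	MRT1,MY014,SNTX27	1	1	PX:1
TJP1	ZO-1	1	3	GuKc:1,SH3:1,ZU5:1
TJP2	ZO-2	1	3	GuKc:1,SH3:1
NEB1	PPP1R9A,NEURABIN-1	1	1	
NEB2	PPP1R9B,NEURABIN-2,SPINOPHILIN	1	1	
PDZD8	PDZK8	1	1	
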