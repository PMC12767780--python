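np_symbol	np_flybase_id	npr_symbol	npr_flybase_id
Akh	FBgn0004552	AkhR	FBgn0025595
AstA	FBgn0015591	AstA-R1	FBgn0266429
AstA	FBgn0015591	AstA-R2	FBgn0039595
AstC	FBgn0032336	AstC-R1	FBgn0036790
AstC	FBgn0032336	AstC-R2	FBgn0036789
burs	FBgn0038901	rk	FBgn0003255
Capa	FBgn0039722	CapaR	FBgn0039396
Capa	FBgn0039722	PK1-R	FBgn0038201
CCHa1	FBgn0038199	CCHa1-R	FBgn0050106
CCHa2	FBgn0038147	CCHa2-R	FBgn0033058
CNMa	FBgn0035282	CNMaR	FBgn0053696
CRZ	FBgn0013767	CrzR	FBgn0036278
CCAP	FBgn0039007	CCAP-R	FBgn0039396
Dh31	FBgn0032048	Dh31-R	FBgn0052843
Dh31	FBgn0032048	hector	FBgn0030437
Dh44	FBgn0012344	Dh44-R1	FBgn0033932
Dh44	FBgn0012344	Dh44-R2	FBgn0033744
ETH	FBgn0028738	ETHR	FBgn0038874
FMRFamide	FBgn0000715	FMRFaR	FBgn0035385
Gpb5	FBgn0063368	Lgr1	FBgn0016650
Hug	FBgn0028374	PK2-R2	FBgn0038139
Hug	FBgn0028374	PK2-R1	FBgn0038140
Ilp1	FBgn0044051	InR	FBgn0283499
ilp2	FBgn0036046	InR	FBgn0283499
ilp3	FBgn0044050	InR	FBgn0283499
ilp4	FBgn0044049	InR	FBgn0283499
ilp5	FBgn0044048	InR	FBgn0283499
ilp6	FBgn0044047	InR	FBgn0283499
ilp7	FBgn0044046	Lgr4	FBgn0085440
ilp8	FBgn0036690	Lgr3	FBgn0039354
Lk	FBgn0028418	Lkr	FBgn0035610
Lst	FBgn0034140	PK1-R	FBgn0038201
Ms	FBgn0011581	MsR1	FBgn0035331
Ms	FBgn0011581	MsR2	FBgn0264002
natalisin	FBgn0085417	TkR86C	FBgn0004841
NPF	FBgn0027109	NPFR	FBgn0037408
Nplp1	FBgn0035092	Gyc76C	FBgn0266136
PDF	FBgn0023178	Pdfr	FBgn0260753
Proctolin	FBgn0045038	Proc-R	FBgn0029723
PTTH	FBgn0013323	torso	FBgn0021796
RYamide	FBgn0085512	Rya-R	FBgn0004842
Acp26Aa	FBgn0002855	SPR	FBgn0029768
sNPF	FBgn0032840	sNPF-R	FBgn0036934
SIFa	FBgn0053527	SIFaR	FBgn0038880
Dsk	FBgn0000500	CCKLR-17D1	FBgn0259231
Dsk	FBgn0000500	CCKLR-17D3	FBgn0030954
Tk	FBgn0037976	TkR99D	FBgn0004622
Trissin	FBgn0038343	TrissinR	FBgn0085410
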