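np_symbol	npr_symbol
AstA	AstA-R1
AstA	AstA-R2
AstC	AstC-R1
AstC	AstC-R2
Capa	CapaR
Crz	CrzR
FMRFa	FMRFaR
NPF	NPFR
Natalisin	PK1-R
Natalisin	TkR86C
Pdf	Pdfr
SIFa	SIFaR
sNPF	sNPF-R
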