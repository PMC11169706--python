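name	lipid_class	formula	confirmation
LPC(O-16:1)	LPC-O	C24H50NO6P	headgroup (PC)
LPC(16:0)	LPC	C24H50NO7P	headgroup (PC)
LPC(O-18:2)	LPC-O	C26H52NO6P	headgroup (PC)
LPC(18:1)	LPC	C26H52NO7P	headgroup (PC)
PC(32:1)	PC	C40H78NO8P	chains PC(16:0/16:1)
PC(34:1)	PC	C42H82NO8P	lock mass species
PC(36:4)	PC	C44H80NO8P	chains PC(16:0/20:4)
SM(d40:1)	SM	C45H91N2O6P	headgroup (PC)
PC(36:1)	PC	C44H86NO8P	chains PC(18:0/18:1)
PC(38:6)	PC	C46H80NO8P	chains PC(16:0/22:6)
PC(38:4)	PC	C46H84NO8P	chains PC(18:0/20:4)
PC(36:2)	PC	C44H84NO8P	chains PC(18:1/18:1)
PC(40:6)	PC	C48H84NO8P	chains PC(18:0/22:6)
PC(40:4)	PC	C48H88NO8P	chains PC(16:0/24:4)
SM(d42:2)	SM	C47H93N2O6P	headgroup (PC)
HexCer(42:2;O3)	HexCer	C48H91NO9	tentative (no MS/MS)
HexCer(42:1;O3)	HexCer	C48H93NO9	tentative (no MS/MS)
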