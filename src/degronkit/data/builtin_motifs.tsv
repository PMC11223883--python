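motif_id	name	pattern	location_class	pathway	source
NT_R1	Arg/N type-1 primary destabilizing N-terminus (basic)	[RKH]	N_TERMINAL	Arg/N	Bachmair et al. 1986; Varshavsky 2019 (PNAS 116:358)
NT_R2	Arg/N type-2 primary destabilizing N-terminus (bulky hydrophobic)	[FWYLI]	N_TERMINAL	Arg/N	Bachmair et al. 1986; Varshavsky 2019 (PNAS 116:358)
NT_SEC	Arg/N secondary destabilizing N-terminus (arginylation substrate)	[DE]	N_TERMINAL	Arg/N	Varshavsky 2019 (PNAS 116:358)
NT_TER	Arg/N tertiary destabilizing N-terminus (deamidation/oxidation substrate)	[NQC]	N_TERMINAL	Arg/N	Varshavsky 2019 (PNAS 116:358)
CT_GG	C-terminal diglycine C-degron (CRL2-KLHDC2)	GG	C_TERMINAL	C-degron:-GG	Koren et al. 2018 (Cell 173:1622); Rusnac et al. 2018
CT_RG	C-terminal -RG C-degron (CRL2-KLHDC3)	RG	C_TERMINAL	C-degron:-RG	Koren et al. 2018 (Cell 173:1622)
CT_RXXG	C-terminal -RxxG C-degron (CRL2-APPBP2)	RxxG	C_TERMINAL	C-degron:-RxxG	Koren et al. 2018 (Cell 173:1622)
CT_EE	C-terminal -EE C-degron (CRL4-DCAF12)	EE	C_TERMINAL	C-degron:-EE	Koren et al. 2018 (Cell 173:1622)
CT_R	C-terminal arginine C-degron (CRL2-FEM1A/B/C)	R	C_TERMINAL	C-degron:-R	Koren et al. 2018 (Cell 173:1622); Yan et al. 2021
CT_VX	C-terminal valine-at-penultimate C-degron family	Vx	C_TERMINAL	C-degron:-VX	Koren et al. 2018 (Cell 173:1622)
CT_A	C-terminal alanine C-degron	A	C_TERMINAL	C-degron:-A	Koren et al. 2018 (Cell 173:1622); Lin et al. 2018
IN_DBOX	APC/C destruction box (D-box)	RxxLxx[LIVM]x[ND]	INTERNAL	APC/C D-box	Glotzer et al. 1991; Davey & Morgan 2016
IN_KEN	APC/C KEN box	KEN	INTERNAL	APC/C KEN	Pfleger & Kirschner 2000
IN_ABBA	APC/C ABBA motif	Fx[ILV][FY]x[DE]	INTERNAL	APC/C ABBA	Di Fiore et al. 2015
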