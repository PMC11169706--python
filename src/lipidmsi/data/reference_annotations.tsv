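exp_mz	ppm_error	name	adduct	confirmation	fc_HC	fc_OC	fc_WM	fc_GM	fc_CC	models
480.3452	0.66	LPC(O-16:1)	[M+H]+	PC	1.70	1.35	2.61	1.69	2.03	WM,GM,OC,CC
496.3399	0.33	LPC(16:0)	[M+H]+	PC	1.27	1.20	1.28	1.23	1.29	HC,OC,WM,GM,CC
506.3609	0.86	LPC(O-18:2)	[M+H]+	PC	1.74	0.76	2.64	2.50	1.70	WM,OC
522.3559	0.83	LPC(18:1)	[M+H]+	PC	1.49	1.43	1.22	1.45	1.20	GM,OC
732.5539	0.13	PC(32:1)	[M+H]+	PC(16:0/16:1)	1.05	0.90	1.03	0.96	1.06	OC
782.5690	-0.50	PC(36:4)	[M+H]+	PC(16:0/20:4)	1.01	0.99	1.03	1.00	1.03	WM
787.6688	0.00	SM(d40:1)	[M+H]+	PC	0.45	1.48	1.47	1.18	2.10	WM
788.6162	-0.24	PC(36:1)	[M+H]+	PC(18:0/18:1)	0.93	0.96	0.97	1.02	0.96	HC
806.5688	-0.81	PC(38:6)	[M+H]+	PC(16:0/22:6)	0.97	1.06	0.99	1.05	1.00	OC
810.6009	0.16	PC(38:4)	[M+H]+	PC(18:0/20:4)	0.97	0.95	0.99	0.97	0.97	OC
824.5564	-0.21	PC(36:2)	[M+K]+	PC(18:1/18:1)	0.84	0.95	0.83	0.88	0.84	WM
826.5720	-0.36	PC(36:1)	[M+K]+	PC(18:0/18:1)	0.83	0.92	0.88	0.89	0.92	WM,CC
834.6010	0.26	PC(40:6)	[M+H]+	PC(18:0/22:6)	0.91	0.96	0.96	1.00	0.95	HC
838.6319	-0.22	PC(40:4)	[M+H]+	PC(16:0/24:4)	0.94	0.84	1.01	0.95	1.06	OC
851.6403	0.04	SM(d42:2)	[M+K]+	PC	0.45	1.17	0.99	1.03	1.07	HC
864.6329	0.42	HexCer(42:2;O3)	[M+K]+	not conclusive	0.70	ND	1.33	1.80	1.34	CC
866.6479	-0.29	HexCer(42:1;O3)	[M+K]+	not conclusive	0.88	0.62	1.21	1.73	1.31	GM,WM,CC
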