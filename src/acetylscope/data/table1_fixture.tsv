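symbol	fc	binding_code
Dusp14	13.17	4.35
Peli1	10.64	4.97
Npas4	9.04	3.97
Prodh2	6.95	4.24
Olr464	6.51	3.71
Nr4a3	6.43	6.01
Fos	6.18	4.77
Nr4a3	4.71	4.39
Egr4	4.62	*
Fzd7	4.22	*
Pkp2	3.79	NC
Nptx2	3.77	2.44
Inhba	3.71	*
Dhrs9	3.54	NC
Hcrt	3.08	3.07
Egr2	3.08	3.49
Arc	2.88	NC
Junb	2.36	*
Taar8c	2.33	*
Nts	2.32	2.67
Gadd45g	2.21	5.30
Dnajb5	2.03	2.28
Cebpb	1.99	2.75
Tgfb3	1.98	6.55
Egr1	1.89	*
Baz1a	1.89	3.13
Dusp5	1.84	*
Porf1	1.83	2.48
Per1	1.83	3.48
Ptpdc1	1.82	4.24
Mchr1	1.81	3.79
Gpd1	1.80	3.70
Abcc10	1.78	5.25
Crem	1.77	3.34
Mafk	1.77	3.21
Vgf	1.76	3.67
Sstr4	1.75	3.86
Gadd45b	1.72	3.26
Snf1lk	1.72	3.07
Asb1	1.71	*
Pip3ap	1.70	*
Stag3	-1.85	*
Gpr149	-1.85	NC
Vegfc	-1.90	-1.49
Jag1	-1.94	-3.50
Olr990	-4.34	*
Amy1	-4.54	*
Tshr	-4.85	*
Dao1	-4.94	NC
Plg	-5.37	*
Olr1463	-5.61	NC
Olr462	-5.87	*
Fshr	-6.06	*
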