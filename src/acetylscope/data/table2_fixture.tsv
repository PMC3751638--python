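symbol	fc	binding_code
Olr577	6.39	*
Npb	5.70	4.22
Plagl2	4.67	*
Cpt1b	3.91	*
Ppef2	3.07	2.95
Gpr143	2.88	4.88
Nr4a3	2.79	4.22
Foxa3	2.60	NC
Olr734	2.28	*
Olfml2a	-1.71	NC
Zfp533	-1.73	*
Pard3	-1.74	-3.94
Tle4	-1.75	-4.22
Bcar3	-1.76	-2.94
Plag1	-1.76	*
Rcn1	-1.81	*
Gpcr12	-1.81	NC
Arl6	-1.87	NC
Prkcm	-1.88	*
Clcn1	-1.90	*
Jag1	-1.94	-3.50
Fbxo15	-1.96	*
Bmp2	-1.99	-3.14
Cd44	-2.01	*
Rims2	-2.13	-3.50
Gpr149	-2.14	-3.23
Spdya	-2.35	NC
Plin	-2.47	*
Stag3	-2.51	*
Clca3	-3.77	*
Cldn22	-3.89	NC
Nek1	-4.36	NC
Olr990	-4.50	*
Ctcfl	-5.45	*
Sdfr2	-6.02	*
Traf4af1	-8.83	NC
Plg	-9.93	*
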