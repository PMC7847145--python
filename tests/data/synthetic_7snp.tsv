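sample_id	snp1	snp2	snp3	snp4	snp5	snp6	snp7	phenotype
s1	2	1	1	1	0	1	1	1
s2	2	0	0	0	1	1	1	1
s3	1	1	1	2	0	1	2	1
s4	0	1	0	1	2	1	2	0
s5	1	2	1	0	0	0	1	1
s6	2	1	1	1	0	0	0	1
s7	0	1	2	0	1	0	2	0
s8	2	1	0	0	0	1	0	1
s9	0	2	0	2	1	2	0	0
s10	0	2	0	0	0	1	0	1
s11	2	0	1	0	2	0	0	0
s12	1	2	0	2	0	0	2	1
s13	0	0	0	1	0	2	0	0
s14	2	0	2	0	2	2	1	1
s15	2	0	2	2	2	0	1	1
s16	2	0	2	2	2	0	2	1
s17	2	2	2	2	0	2	1	1
s18	1	2	1	1	2	1	1	1
s19	2	1	1	1	0	1	2	1
s20	2	0	0	2	0	2	0	0
s21	2	0	1	1	2	0	1	1
s22	0	2	2	2	0	0	2	1
s23	2	2	0	1	0	0	2	1
s24	0	2	1	1	1	1	2	0
s25	0	0	0	0	1	0	0	1
s26	1	0	0	1	0	1	1	0
s27	2	0	2	2	1	2	0	1
s28	0	1	1	1	1	0	1	0
s29	2	1	2	1	0	1	1	1
s30	0	0	0	2	0	0	0	0
s31	0	1	0	2	2	2	1	0
s32	2	2	0	1	1	1	1	0
s33	2	2	2	2	1	0	1	0
s34	2	0	1	0	2	0	0	1
s35	2	1	0	2	1	0	0	0
s36	1	0	0	1	1	1	2	1
s37	0	2	1	0	0	2	0	1
s38	2	0	0	2	0	2	1	0
s39	0	0	0	0	1	0	1	1
s40	0	0	2	2	1	1	1	1
s41	2	2	0	1	0	1	1	1
s42	2	0	2	2	1	1	0	1
s43	2	1	1	1	2	2	2	0
s44	0	2	0	2	1	2	2	0
s45	1	1	2	1	0	0	1	0
s46	2	2	0	2	2	1	1	0
s47	1	2	2	0	1	0	2	0
s48	2	2	2	0	0	0	0	1
s49	0	2	1	2	1	2	0	0
s50	2	0	0	1	1	1	2	1
s51	1	1	2	0	0	2	0	1
s52	0	0	1	1	2	0	1	1
s53	0	1	2	1	0	2	0	1
s54	2	2	1	0	0	0	0	1
s55	0	2	1	1	1	0	0	0
s56	0	0	0	2	2	2	2	1
s57	2	1	2	2	0	0	1	1
s58	1	0	0	0	0	1	1	0
s59	2	1	1	2	0	0	2	1
s60	0	2	2	2	0	1	0	0
s61	0	1	1	2	2	0	1	0
s62	1	1	1	2	0	2	0	1
s63	0	2	2	0	2	2	0	0
s64	1	1	2	2	1	0	1	1
s65	2	0	2	0	1	2	2	1
s66	1	0	1	1	1	1	1	1
s67	1	0	2	1	2	2	0	1
s68	2	1	1	2	1	1	0	1
s69	2	1	2	1	0	0	2	1
s70	0	1	0	0	0	1	1	0
s71	1	2	2	1	1	2	0	1
s72	0	2	1	0	0	0	2	1
s73	0	0	1	0	2	1	0	1
s74	1	0	0	1	2	0	0	1
s75	1	1	2	2	1	2	0	0
s76	0	2	2	1	2	0	0	0
s77	1	0	0	2	0	1	0	0
s78	1	1	0	0	1	0	2	0
s79	0	0	0	0	0	1	2	0
s80	1	2	2	1	2	0	1	1
s81	1	1	2	1	0	1	0	1
s82	2	0	2	1	1	2	1	1
s83	0	0	1	1	2	0	2	1
s84	2	2	2	0	0	2	2	1
s85	1	2	0	1	1	2	0	1
s86	1	2	2	2	0	2	2	1
s87	0	0	2	2	1	2	1	1
s88	2	2	0	0	2	1	1	0
s89	0	2	1	2	1	2	0	0
s90	1	0	1	1	1	1	0	1
s91	1	1	1	0	2	2	2	0
s92	1	1	0	0	0	0	0	1
s93	2	0	2	0	0	1	0	0
s94	2	2	0	1	0	1	2	1
s95	1	0	0	0	2	0	1	0
s96	0	0	1	1	0	0	1	0
s97	2	1	1	0	1	2	1	0
s98	1	2	0	2	1	2	0	0
s99	1	2	1	1	2	0	1	0
s100	2	0	2	2	2	0	1	1
s101	1	0	1	1	1	2	2	1
s102	2	0	1	0	0	2	0	0
s103	1	1	2	0	1	0	2	0
s104	1	2	1	2	0	2	0	1
s105	2	0	0	1	2	0	2	1
s106	1	2	0	1	2	1	1	0
s107	2	0	1	1	1	2	1	1
s108	0	2	0	0	0	2	1	1
s109	0	1	2	0	1	1	0	0
s110	2	1	0	1	2	0	1	0
s111	2	2	1	1	0	2	1	1
s112	0	0	1	1	1	1	2	1
s113	2	1	2	0	0	0	1	1
s114	1	1	1	2	2	2	2	0
s115	2	2	1	0	0	0	0	1
s116	1	1	1	0	0	0	2	1
s117	1	1	2	2	1	0	2	0
s118	1	2	2	2	2	2	0	0
s119	0	0	0	1	2	0	1	1
s120	2	0	1	0	2	2	1	0
s121	1	1	0	2	1	0	1	0
s122	0	0	0	1	2	1	2	1
s123	0	0	0	2	1	1	1	0
s124	0	1	1	2	2	2	2	1
s125	0	2	1	2	0	0	2	1
s126	2	1	0	1	0	0	1	1
s127	1	0	0	0	0	0	1	0
s128	1	2	1	2	1	2	1	0
s129	1	0	1	0	2	2	2	1
s130	1	2	2	1	2	2	1	0
s131	0	1	0	0	1	1	2	0
s132	1	2	0	2	1	2	1	0
s133	1	0	0	0	2	0	2	1
s134	0	1	2	1	0	1	1	1
s135	0	0	1	0	2	0	1	1
s136	0	2	1	0	0	2	1	1
s137	2	2	0	1	1	2	1	0
s138	2	0	0	0	2	0	0	1
s139	2	0	1	1	2	1	0	1
s140	0	2	1	2	2	2	0	0
s141	0	1	0	1	2	0	1	0
s142	0	2	2	1	1	0	1	0
s143	1	0	2	1	0	0	1	0
s144	0	2	1	2	1	2	1	0
s145	1	0	0	2	1	0	0	1
s146	0	2	1	2	0	0	0	1
s147	0	2	0	2	1	0	1	0
s148	0	0	2	1	1	0	2	1
s149	0	0	1	0	2	0	2	1
s150	0	1	1	1	1	1	0	0
s151	0	0	2	1	1	1	1	1
s152	1	0	1	0	0	2	2	1
s153	1	1	0	1	0	0	1	1
s154	0	0	0	1	1	2	2	1
s155	0	2	1	2	2	1	2	0
s156	1	0	1	0	2	0	0	1
s157	1	1	1	1	1	1	1	0
s158	1	0	0	0	1	0	0	1
s159	0	2	2	0	2	0	2	0
s160	0	2	2	2	1	2	1	0
s161	1	1	2	0	2	2	1	0
s162	1	2	2	0	2	0	1	1
s163	1	2	0	1	0	0	0	1
s164	1	1	1	0	2	2	0	0
s165	0	0	0	0	0	2	2	0
s166	0	1	1	1	2	0	0	0
s167	2	1	2	0	1	1	0	0
s168	1	0	1	0	2	0	1	1
s169	2	2	0	2	0	2	0	1
s170	2	1	1	1	0	2	1	1
s171	2	1	1	1	1	1	0	0
s172	0	1	1	2	2	2	0	0
s173	0	0	2	2	2	0	1	1
s174	1	0	1	2	1	1	0	1
s175	1	0	1	0	1	2	0	1
s176	2	1	1	2	1	0	1	0
s177	1	0	1	2	1	2	1	0
s178	0	0	1	1	0	1	0	0
s179	0	1	2	1	2	0	0	0
s180	0	2	1	1	2	2	1	0
s181	0	1	1	2	2	1	1	1
s182	2	1	2	2	2	2	1	0
s183	0	2	1	2	1	1	0	0
s184	2	1	1	2	2	1	0	0
s185	2	2	1	1	2	1	2	0
s186	0	2	1	0	2	2	2	0
s187	2	2	0	1	1	0	2	0
s188	2	1	2	0	2	0	2	1
s189	0	0	1	1	0	2	1	0
s190	0	2	1	2	0	1	2	1
s191	2	0	0	0	1	2	0	1
s192	0	2	0	2	0	0	0	1
s193	2	2	0	1	2	0	2	0
s194	2	0	0	1	1	2	0	1
s195	2	2	2	0	1	1	2	0
s196	2	0	2	2	2	1	0	1
s197	1	0	2	0	1	2	2	1
s198	1	1	0	0	2	0	2	0
s199	1	1	2	1	1	0	0	0
s200	1	1	1	1	1	1	0	0
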