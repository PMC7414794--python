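gene	accession	orf_bp	sp_start	sp_end	mw_kda	pi	class
EbalOBP1	MT247215	783	1	19	29.54	6.22	Plus-C
EbalOBP2	MT247216	762	1	19	29.96	7.55	Classic
EbalOBP3	MT247217	5'missing	-	-	23.89	7.51	Plus-C
EbalOBP4	MT247218	585	1	27	21.75	6.08	Plus-C
EbalOBP5	MT247219	456	1	15	17.72	5.33	Minus-C
EbalOBP6	MT247220	474	1	19	17.76	5.56	Classic
EbalOBP7	MT247221	471	1	15	18.54	4.91	Minus-C
EbalOBP8	MT247222	468	1	16	18.29	5.01	Minus-C
EbalOBP9	MT247223	471	1	15	18.25	5.59	Minus-C
EbalOBP10	MT247224	462	1	19	17.52	4.68	Classic
EbalOBP11	MT247225	456	1	15	17.66	5.33	Minus-C
EbalOBP12	MT247226	453	1	16	17.3	6.09	Classic
EbalOBP13	MT247227	450	1	24	16.57	4.86	Classic
EbalOBP14	MT247228	450	1	17	16.62	5.02	Minus-C
EbalOBP15	MT247229	450	1	15	17.43	6.17	Minus-C
EbalOBP16	MT247230	447	1	15	17.47	5.32	Minus-C
EbalOBP17	MT247231	444	1	24	16.48	8.17	Classic
EbalOBP18	MT247232	441	1	15	17.01	5.91	Minus-C
EbalOBP19	MT247233	441	1	19	16.51	4.58	Classic
EbalOBP20	MT247234	441	1	20	16.99	5.52	Classic
EbalOBP21	MT247235	441	1	16	17.03	5.1	Minus-C
EbalOBP22	MT247236	438	1	23	16.25	8.16	Classic
EbalOBP23	MT247237	435	1	20	16.72	5.44	Classic
EbalOBP24	MT247238	432	1	18	15.42	5.82	Classic
EbalOBP25	MT247239	429	1	18	16.57	9.1	Classic
EbalOBP26	MT247240	429	1	17	16.24	7.56	Classic
EbalOBP27	MT247241	375	1	18	13.87	5.31	Classic
EbalOBP28	MT247242	417	1	19	15.69	5	Classic
EbalOBP29	MT247243	417	1	23	15.79	5.75	Classic
EbalOBP30	MT247244	414	1	20	15.73	5.71	Classic
EbalOBP31	MT247245	5'missing	-	-	15.86	5.16	Classic
EbalOBP32	MT247246	408	1	18	14.95	4.45	Classic
EbalOBP33	MT247247	399	1	18	14.41	6.13	Classic
EbalOBP34	MT247248	375	1	18	14.13	5.31	Classic
EbalOBP35	MT247249	396	1	25	14.94	5.94	Classic
EbalOBP36	MT247250	393	1	18	14.79	5.96	Classic
EbalOBP38	MT247251	390	1	18	14.65	6.57	Classic
EbalOBP39	MT247252	390	1	19	14.54	4.69	Classic
EbalOBP40	MT247253	390	1	18	14.34	5.77	Classic
EbalOBP41	MT247254	381	1	18	13.85	5.45	Classic
EbalOBP42	MT247257	-	-	-	-	-	-
EbalOBP43	MT247258	-	-	-	-	-	-
EbalOBP45	MT247255	-	-	-	-	-	-
EbalOBP49	MT247259	-	-	-	-	-	-
EbalCSP1	MT247256	-	-	-	-	-	CSP
EbalCSP2	MT247210	384	1	18	14.47	8.81	CSP
EbalCSP3	MT247211	642	1	20	24.42	9.16	CSP
EbalCSP4	MT247212	966	1	20	35.34	8.83	CSP
EbalCSP5	MT247213	339	1	26	12.7	10.05	CSP
EbalCSP6	MT247214	429	1	19	16.18	5.26	CSP
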