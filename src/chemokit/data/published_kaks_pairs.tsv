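pair	family	ka	ks	ka_ks
EbalOBP1-EcorOBP2	OBP	0.24416	2.34607	0.10418
EbalOBP1-EcorOBP3	OBP	0.49258	3.21105	0.15340
EbalOBP3-EcorOBP4	OBP	0.23802	1.83007	0.13006
EbalOBP7-EcorOBP6	OBP	0.30803	2.93471	0.10496
EbalOBP8-EcorOBP6	OBP	0.30793	1.72943	0.17803
EbalOBP9-EcorOBP6	OBP	0.25755	2.17604	0.11836
EbalOBP14-EcorOBP11	OBP	0.31790	0.81588	0.38964
EbalOBP17-EcorOBP14	OBP	0.00285	0.10202	0.02789
EbalOBP18-EcorOBP7	OBP	0.37527	3.53355	0.10620
EbalOBP21-EcorOBP13	OBP	0.23399	1.12186	0.20858
EbalOBP23-EcorOBP15	OBP	0.02784	0.25389	0.10966
EbalOBP24-EcorOBP17	OBP	0.20356	1.60117	0.12713
EbalOBP27-EcorOBP23	OBP	0.00329	0.06645	0.04947
EbalOBP31-EcorOBP20	OBP	0.05299	1.24151	0.04268
EbalOBP32-EcorOBP25	OBP	0.23657	1.24667	0.18976
EbalOBP33-EcorOBP27	OBP	0.00004	0.03924	0.00000
EbalOBP34-EcorOBP23	OBP	0.18258	0.79731	0.22900
EbalOBP35-EcorOBP23	OBP	0.17179	0.91638	0.18746
EbalOBP36-EcorOBP32	OBP	0.00313	0.01555	0.20153
EbalOBP40-EcorOBP33	OBP	0.01126	0.02771	0.40659
EbalCSP2-EcorCSP1	CSP	0.02895	0.56276	0.05144
EcorCSP5-EbalCSP3	CSP	0.09714	0.73580	0.13201
EbalCSP3-EcorCSP6	CSP	0.17875	1.10239	0.16215
EbalCSP3-EcorCSP7	CSP	0.20553	1.12375	0.18292
EbalCSP4-EcorCSP5	CSP	0.20166	1.16534	0.17305
EbalCSP4-EcorCSP6	CSP	0.28812	1.52324	0.18915
EbalCSP4-EcorCSP7	CSP	0.13822	0.90006	0.15357
EbalCSP5-EcorCSP4	CSP	0.01257	0.56174	0.02237
EbalCSP6-EcorCSP2	CSP	0.06799	0.70548	0.09637
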