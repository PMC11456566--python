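gene	Control	BL-R Pre	BL-R Post	BL-NR Pre	BL-NR Post
IGHG3	16104.79	9435.45	82198.04	1648.41	7598.11
IGHM	88968.79	28365.72	62260.41	36947.57	43268.96
CD14	5778.63	1715.27	12184.44	3109.39	3771.74
FABP4	8830.79	776.97	7072.81	3947.00	3899.05
CRHBP	5048.48	1780.38	3809.01	5571.75	8213.73
CD24	4065.58	421.05	3622.90	239.80	1635.12
LPL	1425.19	269.02	1783.08	657.64	3369.90
RGS1	3628.81	1542.55	5145.90	4721.61	4405.77
NNMT	942.07	194.09	1004.29	529.55	2819.85
EPAS1	1703.03	227.54	1799.50	780.56	1646.70
LTB	4088.90	2072.56	2084.41	703.23	2654.48
CD79B	14484.97	2412.57	1666.90	1515.04	4032.88
COL5A1	5024.98	1167.26	1017.97	778.64	1940.60
CAV1	312.86	223.45	1187.46	562.42	610.42
LEF1	5425.96	697.48	627.26	79.38	1016.49
VPREB1	8653.12	838.01	377.65	118.67	1392.64
POU2AF1	3184.54	244.71	579.62	14.78	473.98
FCN1	33193.86	5406.90	19291.68	20524.88	7421.06
SPARCL1	1199.84	154.30	847.43	604.10	651.28
LRIG1	3738.12	479.57	537.37	459.50	1059.65
GEM	131.59	429.96	1000.10	513.93	312.95
BLNK	1970.59	1207.32	1492.85	270.21	297.82
RIMS3	1807.37	99.94	154.38	78.88	325.03
AKAP12	5949.82	549.22	1573.43	2254.97	1480.03
QRSL1	2735.24	2127.55	2005.38	1591.73	1959.36
STAG3	876.34	550.38	560.50	188.22	378.26
P4HA2	576.43	135.73	152.42	164.42	323.24
VPREB3	3576.61	287.05	58.75	15.50	378.48
CRIM1	1080.04	389.77	481.16	943.00	909.27
PAX5	1693.54	36.27	6.42	4.14	68.51
BACH2	2928.52	250.45	162.96	281.25	354.82
CCL20	22.60	25.58	32.13	100.11	60.63
DNTT	46819.78	10225.85	7005.71	2725.81	5589.69
MME	5154.99	238.26	198.33	1113.70	782.56
HES1	381.46	571.60	276.11	436.19	296.29
ISG20	3444.08	1371.75	1766.16	2678.35	1827.40
ID3	1957.32	1599.76	998.57	1026.62	1153.00
IGLL1	25769.20	15318.90	12693.64	5020.73	7141.67
SSBP2	6413.97	4926.93	4279.38	5677.61	5791.00
SKIL	3087.93	2242.85	1847.12	1960.56	1805.89
C6orf62	8376.06	7788.41	9180.92	9785.68	7653.82
HLA-DQA1	2865.25	1941.78	3661.78	4099.04	1635.60
PPFIBP1	1055.90	1245.71	761.11	1464.38	1015.21
CXCR4	24631.48	11656.08	16431.12	23169.72	17397.25
NR4A3	1000.55	348.15	605.17	2596.13	611.65
HSPA1B	1005.70	1081.68	1386.80	3446.61	1355.19
ID1	2345.93	3871.06	2496.06	3319.61	2543.26
CD9	8324.22	3264.77	4757.83	10320.21	6274.36
CDK9	11139.21	6832.92	4588.04	6137.37	5560.83
HLA-DQB1	9128.92	4356.27	6704.73	11541.73	5338.77
BTG1	21182.78	6520.01	9899.51	18182.66	10877.76
PDE4B	6622.82	6806.24	8811.91	14083.89	7035.40
NR4A1	5499.83	10022.47	10095.90	14649.17	9185.77
NR4A2	5204.74	3324.52	5709.50	16996.50	5647.31
TCF4	15473.58	10846.44	7542.07	15785.89	7603.98
ZFP36L2	263541.21	113923.29	84431.10	144233.36	152912.72
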