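gene	group	mean	cv_pct	mfc	housekeeping
ACT1	Root	280.27	17.25	1.56	1
ACT1	Stem	265.46	13.13	1.39	1
ACT1	Leaf	156.12	36.75	2.39	1
ACT1	LP	283.56	12.10	1.26	1
ACT1	FS	249.51	34.39	2.01	1
ACT1	GFS	219.06	50.76	3.03	1
ACT1	RFS	229.38	21.21	1.53	1
ACT1	RGS	188.24	40.66	2.43	1
GAPDH	Root	517.62	26.50	1.91	1
GAPDH	Stem	392.02	14.19	1.40	1
GAPDH	Leaf	392.02	34.86	2.11	1
GAPDH	LP	422.62	18.40	1.44	1
GAPDH	FS	478.44	31.78	1.88	1
GAPDH	GFS	335.02	19.14	1.48	1
GAPDH	RFS	416.59	53.80	2.38	1
GAPDH	RGS	434.14	33.16	1.80	1
18SrRNA	Root	2726.48	48.92	2.77	1
18SrRNA	Stem	1563.01	36.53	2.70	1
18SrRNA	Leaf	2829.04	88.21	8.76	1
18SrRNA	LP	4088.88	83.35	4.49	1
18SrRNA	FS	1527.74	32.45	1.97	1
18SrRNA	GFS	2449.55	88.20	5.18	1
18SrRNA	RFS	2167.32	45.18	2.37	1
18SrRNA	RGS	1630.74	75.91	3.35	1
UBQ	Root	354.75	13.56	1.48	1
UBQ	Stem	446.27	21.62	1.67	1
UBQ	Leaf	254.84	55.54	4.99	1
UBQ	LP	340.27	72.62	6.91	1
UBQ	FS	388.34	31.01	1.86	1
UBQ	GFS	338.54	21.85	1.56	1
UBQ	RFS	285.81	42.02	2.48	1
UBQ	RGS	406.81	3.06	1.06	1
bTUB	Root	142.86	33.36	2.41	1
bTUB	Stem	155.96	53.08	3.09	1
bTUB	Leaf	135.11	79.35	4.51	1
bTUB	LP	234.19	56.06	3.87	1
bTUB	FS	119.91	10.99	1.25	1
bTUB	GFS	109.24	42.01	2.25	1
bTUB	RFS	126.68	52.14	2.70	1
bTUB	RGS	133.19	36.77	2.14	1
aTUB	Root	248.24	16.39	1.46	1
aTUB	Stem	250.74	26.37	1.79	1
aTUB	Leaf	162.62	15.59	1.32	1
aTUB	LP	245.46	42.05	2.36	1
aTUB	FS	210.32	5.54	1.11	1
aTUB	GFS	194.88	20.96	1.53	1
aTUB	RFS	193.14	28.60	1.81	1
aTUB	RGS	258.86	27.35	1.76	1
CYP	Root	121.36	41.12	2.57	1
CYP	Stem	116.79	22.39	1.54	1
CYP	Leaf	75.50	45.42	3.29	1
CYP	LP	87.57	44.66	2.52	1
CYP	FS	109.78	24.99	1.65	1
CYP	GFS	88.71	23.95	1.59	1
CYP	RFS	111.44	74.70	37.10	1
CYP	RGS	125.26	20.54	1.52	1
eIF-5A	Root	536.09	17.46	1.50	1
eIF-5A	Stem	460.75	24.78	1.77	1
eIF-5A	Leaf	324.73	12.60	1.38	1
eIF-5A	LP	438.19	28.52	1.75	1
eIF-5A	FS	552.48	27.24	1.76	1
eIF-5A	GFS	386.54	22.44	1.58	1
eIF-5A	RFS	371.38	30.90	1.78	1
eIF-5A	RGS	454.03	26.74	1.73	1
F-box	Root	143.55	15.16	2.50	1
F-box	Stem	80.05	18.83	1.49	1
F-box	Leaf	48.39	23.15	1.92	1
F-box	LP	84.49	73.19	4.59	1
F-box	FS	95.38	66.87	3.80	1
F-box	GFS	75.92	42.88	1.70	1
F-box	RFS	99.56	52.28	3.02	1
F-box	RGS	97.99	34.08	2.04	1
EF-1a	Root	403.63	37.91	2.64	1
EF-1a	Stem	470.07	25.04	1.74	1
EF-1a	Leaf	293.66	31.75	2.18	1
EF-1a	LP	509.99	27.82	1.66	1
EF-1a	FS	435.84	44.13	2.47	1
EF-1a	GFS	286.42	37.61	1.97	1
EF-1a	RFS	364.72	21.18	1.54	1
EF-1a	RGS	348.64	32.12	1.77	1
CDP	Root	133.83	5.11	1.14	0
30SRPS20	Root	121.44	11.58	1.31	0
SAR1	Root	195.68	12.65	1.39	0
6-PG	Root	105.83	14.48	1.49	0
ARF	Root	119.60	17.00	1.41	0
V-ATP	Root	177.53	19.70	1.47	0
V-ATP	Stem	163.71	6.05	1.14	0
ARF	Stem	103.96	6.42	1.19	0
60SRPL13	Stem	187.47	8.03	1.21	0
30SRPS20	Stem	88.88	10.38	1.34	0
QCR	Stem	166.70	10.92	1.24	0
polIIa	Stem	128.55	15.33	1.39	0
TCTP	Leaf	188.49	8.84	1.28	0
QCR	Leaf	112.80	16.32	1.50	0
60SRPL13	Leaf	129.78	19.65	1.49	0
SAR1	Leaf	82.35	19.23	1.50	0
60SRPL13	LP	166.52	5.81	1.12	0
QCR	LP	149.79	17.70	1.43	0
V-ATP	LP	143.11	18.90	1.46	0
V-ATP	FS	151.67	15.47	1.37	0
polIIa	FS	119.79	19.34	1.40	0
ARF	FS	86.04	19.53	1.50	0
polIIa	GFS	117.42	7.60	1.16	0
CDP	GFS	123.19	9.77	1.11	0
CDP	RFS	152.08	16.47	1.34	0
QCR	RFS	157.29	17.92	1.36	0
CDP	RGS	142.48	4.53	1.09	0
polIIa	RGS	160.48	19.30	1.47	0
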