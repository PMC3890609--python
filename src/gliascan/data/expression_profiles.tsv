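upf	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	region
P1	32	25	60	60	62	67	54	31	42	20	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P2	0	7	0	0	15	0	0	15	36	23	PFPQPQLSYSQPQPFRPQQPYPQPQPQY
P3	0	0	18	0	0	0	0	6	0	0	PFPQPQLPYSHPQPFRPQQPYPQPQPQY
P4	0	5	0	0	0	0	0	0	0	0	PFLQPQLPYSQPQPFRPQQPYPQPQPQY
P5	0	0	0	0	0	15	0	0	0	0	PFPQPQLPYSHPQPFRPQQPYPQPQPQY
P6	0	0	0	0	0	9	0	0	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P7	0	5	0	8	9	0	0	0	4	15	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P8	0	0	6	0	0	0	0	0	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P9	0	0	0	0	0	0	19	0	0	3	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P10	0	0	0	14	0	0	0	0	0	0	PFPQLQLPYSQPQPFRPQQPYPQPQPQY
P11	0	0	0	0	3	0	0	0	0	0	PFLPQLPYPQPQPFPPQQPYPQPQPQY
P12	0	0	0	0	0	0	0	0	0	8	PFPQPQLPYSQPQPFRPQQPYPQPQPRY
P13	25	0	0	0	0	0	0	0	0	0	PFPQPQLPYSQPQPFQPQQPYPQPQPQY
P14	0	7	0	0	0	0	0	0	0	0	PFSQPQLPYSQPQPFRPQQPYPQPQPQY
P17	0	0	0	10	0	0	0	0	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P18	20	0	0	0	0	0	0	0	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P19	0	0	0	0	0	0	0	4	0	5	PFPQPQLPYSQPQPFRPQQPYPQPQPHY
P20	0	0	0	0	0	0	7	0	0	0	PFPQPQLPYLQPQPFRPQQPYPQPQPQY
P22	0	0	0	0	0	0	0	0	5	7	PFSQPQLPYLQPQLFRPQQPYPQPQPQY
P23	0	0	0	0	0	0	9	0	0	0	PFPPPQLPYSQPQPFRPQQPYPQPQPQY
P25	7	0	0	0	0	0	0	0	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P27	0	0	0	0	5	0	0	0	0	0	PFPQPQLPYLQPQPFRPQQPYPQPQPQY
P28	0	0	0	0	0	0	0	6	0	0	PFLPQLPYPQPQPFPPQQSYPQPQPQY
P31	0	0	0	4	0	0	0	0	0	0	PFPQPQLPYLQPQPFRPQQPYPQPQPQY
P33	0	0	0	0	0	0	0	3	0	0	PFPPQLPYPQPQSFPPQQPYPQQQPQY
P35	0	0	0	0	0	0	0	0	0	4	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P37	0	0	0	0	0	0	0	4	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P39	0	0	0	0	0	0	0	4	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P42	0	0	0	0	0	0	0	3	0	0	PFPPQLPYPQAQPFPTQQPYPQPQPQY
P43	0	11	0	0	0	0	0	0	0	0	PFPQPQLPYPQPQPFRPQQPYPQPQPQY
P46	0	0	0	0	0	0	0	3	0	0	PFPQPQLPYSQPQPFRPQQPYPQPQPQY
P49	0	9	0	0	0	0	0	0	0	0	PFPPPQLPYSQPQPFRPQQPYPQPQPQY
P55	0	0	0	0	0	0	0	3	0	0	PFPQPQLPYLQPQPFRPQQPYPQPQPQY
P62	0	7	0	0	0	0	0	0	0	0	PFPQPQLPYPQPQPFRPQQPYPQPQPQY
P77	0	4	0	0	0	0	0	0	0	0	PFPQPQLPYPQPQPFRPQQPYPQPQPQY
P82	0	3	0	0	0	0	0	0	0	0	PFPQPQLPYPQPQLPYPQPQPFRPQQPYPQPQPQY
TOTAL	84	83	84	96	94	91	89	82	87	85
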