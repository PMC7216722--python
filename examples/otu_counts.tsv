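sample	OTU1	OTU2	OTU3	OTU4	OTU5	OTU6	OTU7	OTU8	OTU9	OTU10	OTU11	OTU12	OTU13	OTU14	OTU15	OTU16	OTU17	OTU18	OTU19	OTU20	OTU21	OTU22	OTU23	OTU24	OTU25	OTU26	OTU27	OTU28	OTU29	OTU30	OTU31	OTU32	OTU33	OTU34	OTU35	OTU36	OTU37	OTU38	OTU39	OTU40
S1	330	110	39	87	98	47	20	36	10	10	36	17	7	7	17	11	13	11	2	6	14	19	5	4	10	2	6	3	3	4	3	1	0	3	0	2	0	4	2	1
S2	379	59	67	35	66	32	95	25	35	20	11	0	13	3	2	17	14	14	8	4	1	6	7	0	5	23	0	0	0	12	7	0	2	12	2	9	15	0	0	0
S3	349	53	51	109	14	46	9	36	42	27	28	16	39	5	7	3	11	2	14	5	1	1	10	9	6	7	11	9	2	33	0	10	10	15	0	0	10	0	0	0
S4	273	90	43	95	51	46	42	18	25	19	27	21	55	23	0	11	30	7	4	13	4	2	10	13	11	3	0	5	0	2	10	0	15	0	12	1	4	3	7	5
S5	229	105	30	80	35	56	52	32	16	47	3	49	16	20	0	8	27	23	4	24	1	0	4	8	1	2	0	0	17	8	4	5	37	18	2	24	0	10	0	3
S6	234	68	80	169	23	16	28	49	15	62	25	31	12	9	9	0	15	8	33	9	6	1	4	7	5	8	4	4	5	13	0	0	22	1	2	13	2	2	5	1
S7	277	85	80	46	53	13	38	45	21	26	19	34	26	20	27	5	6	28	2	32	6	15	8	1	0	5	14	12	4	7	0	4	6	17	1	0	0	16	0	1
S8	318	61	82	53	34	27	43	8	30	16	19	27	39	20	4	29	7	39	0	4	8	10	8	9	14	3	0	0	0	4	10	11	3	6	1	18	6	3	0	26
S9	342	50	46	157	51	59	7	14	6	19	15	16	25	25	8	6	12	17	6	1	34	11	12	4	8	0	4	2	2	2	0	16	2	2	0	15	4	0	0	0
S10	295	71	44	76	35	27	15	62	38	12	25	34	16	49	5	8	2	8	8	6	27	17	1	4	2	0	16	9	0	16	0	3	32	1	0	0	1	22	13	0
S11	300	47	25	25	109	63	30	26	7	51	9	36	17	4	13	11	34	1	1	1	28	3	3	6	7	1	9	0	28	4	23	3	34	3	18	0	0	1	17	2
S12	260	50	140	27	74	35	12	58	20	25	20	9	17	25	7	30	16	20	28	1	0	17	5	22	3	21	8	3	1	10	3	0	0	14	0	3	2	8	5	1
S13	225	100	50	77	110	41	34	42	26	20	12	23	14	21	7	11	0	11	2	26	7	0	2	0	5	2	0	0	6	0	26	21	0	18	2	1	6	29	21	2
S14	394	86	78	59	21	53	21	27	26	11	15	1	9	1	8	12	45	7	13	8	0	8	3	0	27	3	9	8	7	3	9	0	8	10	0	5	0	3	0	2
S15	220	123	66	43	35	36	16	21	28	24	31	36	54	0	0	21	17	19	1	21	7	22	4	25	3	21	5	13	3	30	0	0	0	6	15	14	8	4	4	4
S16	233	84	81	13	55	69	69	11	15	16	7	70	44	28	32	3	21	24	4	9	13	5	8	8	1	0	2	0	6	2	2	2	0	0	0	5	36	2	0	20
S17	282	79	63	34	25	83	41	33	25	11	4	16	9	18	64	31	9	6	15	3	4	3	0	4	11	17	32	5	10	0	2	9	11	9	6	0	1	7	7	11
S18	267	103	105	37	45	53	19	61	25	4	8	16	13	40	44	1	4	8	12	3	14	0	0	27	4	4	9	29	5	8	7	1	7	7	0	6	0	3	1	0
S19	257	62	87	66	11	93	28	48	15	37	22	49	4	7	5	10	8	6	11	8	18	7	6	7	16	4	5	15	4	10	7	21	0	1	1	31	4	1	5	3
S20	351	72	76	38	25	34	11	25	12	14	2	22	8	31	36	25	18	21	8	3	3	57	2	5	12	22	14	17	10	2	1	0	1	2	0	3	0	6	9	2
S21	265	82	36	91	69	59	35	29	70	19	4	25	14	22	21	7	9	0	18	1	22	6	6	0	0	1	18	3	14	0	4	4	11	8	0	0	0	0	27	0
S22	278	54	60	78	19	120	9	24	20	29	25	19	29	5	7	13	6	17	4	20	5	3	39	1	1	26	0	9	4	6	5	17	28	10	0	0	0	10	0	0
S23	382	57	73	47	46	35	23	26	9	40	15	38	3	7	10	13	12	6	38	2	15	31	5	1	0	7	10	6	21	0	0	1	0	3	1	0	7	1	8	1
S24	258	109	30	74	29	41	23	47	66	49	23	6	19	16	17	51	16	17	13	8	0	5	6	11	4	5	5	2	17	2	6	6	8	3	2	3	0	0	3	0
S25	290	65	86	46	52	10	27	17	20	43	7	18	0	18	31	16	32	53	1	1	2	24	31	0	7	1	0	23	18	7	3	5	0	1	0	40	2	0	0	3
S26	340	79	86	109	30	42	21	34	22	16	61	13	14	7	5	17	17	5	0	3	10	1	0	1	5	1	11	0	14	2	0	1	0	20	5	1	0	7	0	0
S27	229	80	44	41	47	53	8	30	55	50	2	15	15	14	35	14	4	0	19	16	29	6	9	22	15	24	13	43	8	14	0	12	0	0	14	0	14	0	0	6
S28	271	45	99	54	24	27	48	57	34	8	22	42	5	23	34	12	16	28	12	8	1	30	1	2	23	0	1	27	4	2	0	1	0	30	1	1	1	0	3	3
S29	276	118	37	50	16	75	38	34	14	24	26	65	23	8	4	16	10	9	5	23	31	9	1	10	0	3	7	8	2	6	18	19	0	6	0	1	6	0	0	2
S30	254	66	76	63	49	47	25	42	63	52	13	35	5	18	15	16	27	19	12	0	1	6	8	1	24	3	5	5	9	0	4	24	3	2	1	0	5	0	0	2
S31	234	76	49	107	35	67	37	12	4	30	7	70	36	4	5	1	14	5	29	7	0	3	2	35	1	0	13	4	1	2	9	4	14	3	5	22	0	53	0	0
S32	278	83	85	28	57	37	20	26	29	30	7	12	24	38	15	18	9	2	1	3	9	31	0	12	11	12	19	4	30	0	1	40	11	2	0	0	3	8	1	4
S33	318	53	27	38	50	33	49	28	15	20	35	72	17	17	6	15	6	11	7	45	1	33	7	2	5	3	0	6	13	21	4	11	0	2	2	0	18	2	6	2
S34	306	62	40	55	30	24	43	34	54	29	10	21	12	6	53	10	13	7	22	1	30	1	12	4	1	5	2	53	0	2	2	1	19	8	3	2	7	2	11	3
S35	403	76	60	26	38	34	17	48	47	61	17	20	7	11	9	8	4	12	6	14	0	25	1	1	3	6	0	1	0	10	3	5	0	0	1	1	10	14	0	1
S36	279	93	71	32	72	53	44	21	18	16	27	1	16	14	7	20	1	15	15	4	11	17	14	26	3	14	0	48	0	1	8	0	3	0	1	27	0	3	0	5
S37	333	84	19	70	36	47	26	34	20	14	65	32	18	4	6	27	24	13	2	13	21	6	24	6	1	1	3	1	19	0	0	0	0	19	7	0	0	0	2	3
S38	303	61	89	73	17	24	75	27	13	56	7	4	9	17	19	13	16	5	14	38	0	36	23	4	0	12	10	2	2	9	0	1	6	3	4	0	2	3	0	3
S39	255	110	57	63	41	43	53	19	28	5	35	5	23	7	46	17	30	25	16	0	0	5	3	10	3	7	13	22	0	0	5	11	0	0	1	1	6	0	12	23
S40	278	46	77	69	45	70	55	25	65	12	15	14	9	26	3	38	22	11	6	6	7	10	0	10	0	2	26	30	10	0	2	0	5	0	0	2	2	1	1	0
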