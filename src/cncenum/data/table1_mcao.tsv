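reperfusion_time	case	volume_ml	n_cnc	severity	cncs_per_ml_printed
0h	1	0.82	22	/	26.8
0h	2	0.74	13	/	17.6
0h	3	0.4	15	/	37.5
0h	4	0.3	7	/	23.3
0h	5	0.88	26	/	29.5
4h	6	0.35	52	++	148.5
4h	7	0.6	116	++	193.3
4h	8	0.4	65	++	162.5
1d	9	0.3	13	+	43.3
1d	10	0.75	44	+	58.6
1d	11	0.8	58	++	72.5
1d	12	0.43	46	++	107
1d	13	0.5	69	++	138
1d	14	0.5	103	++	206
1d	15	0.55	141	++	256
3d	16	0.5	59	+	118
3d	17	0.6	72	+	120
3d	18	0.55	99	+	180
3d	19	0.7	286	++	408.6
3d	20	0.6	207	++	345
3d	21	0.6	299	++	498.3
3d	22	0.41	166	++	404
3d	23	0.5	257	++	514
3d	24	0.5	350	++	700
7d	25	0.5	21	+	42
7d	26	0.64	61	+	95
7d	27	0.64	62	+	97
7d	28	0.6	69	++	115
7d	29	0.6	75	++	125
7d	30	0.62	79	++	127
7d	31	0.64	87	++	136
7d	32	0.1	17	++	170
10d	33	0.75	72	+	96
10d	34	0.7	86	+	122.8
10d	35	0.3	81	++	270
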