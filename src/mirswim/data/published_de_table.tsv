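name	hist_std	nc_std	log2fc	p_value	sig	mark
miR-122	1.87	5.57	-1.58	7.45E-03	**	Down
miR-1298	32.53	112.40	-1.79	6.38E-18	**	Down
miR-1343	0.75	2.08	-1.47	4.67E-02	*	Down
miR-141	214.33	52.96	2.02	1.01E-15	**	Up
miR-141*	3.55	0.68	2.39	3.24E-02	*	Up
miR-182	58782.66	15810.92	1.89	0	**	Up
miR-183	22358.06	6087.04	1.88	0	**	Up
miR-200a	672.58	163.23	2.04	5.83E-46	**	Up
miR-200a*	31.14	9.00	1.79	1.83E-03	**	Up
miR-200b	1140.91	260.82	2.13	1.32E-81	**	Up
miR-200b*	62.85	17.28	1.86	1.44E-05	**	Up
miR-200c	1671.08	426.85	1.97	3.45E-103	**	Up
miR-2637	7.75	2.18	1.83	3.27E-02	*	Up
miR-263a-5p	6.31	2.47	1.35	4.28E-02	*	Up
miR-2881	30.88	14.38	1.10	1.56E-02	*	Up
miR-34c	770.29	1543.64	-1.00	8.67E-122	**	Down
miR-3897-3p	1.04	5.42	-2.38	1.46E-02	*	Down
miR-4154-3p	3.34	8.76	-1.39	6.13E-03	**	Down
miR-429	582.83	132.63	2.14	5.56E-43	**	Up
miR-4466	1.97	4.60	-1.22	4.14E-02	*	Down
miR-4483	31.42	84.91	-1.43	6.27E-12	**	Down
miR-4492	1.00	3.49	-1.79	4.92E-02	*	Down
miR-4497	10.98	30.54	-1.48	1.29E-05	**	Down
miR-4508	2.58	9.05	-1.81	2.33E-03	**	Down
miR-4510	46.78	9.10	2.36	6.53E-06	**	Up
miR-4651	1.51	6.05	-2.01	7.08E-03	**	Down
miR-483	4.23	8.71	-1.04	1.22E-02	*	Down
miR-5128	0.90	2.23	-1.31	3.95E-02	*	Down
miR-7b	378.58	788.40	-1.06	8.66E-67	**	Down
miR-84a	5.06	13.02	-1.36	3.24E-03	**	Down
miR-96	208.98	48.99	2.09	2.47E-16	**	Up
rno-miR-n006_3p	1.51	0	7.24	8.58E-09	**	Up
rno-miR-n012_5p	0.79	1.84	-1.22	1.89E-03	**	Down
rno-miR-n027_5p	0.90	2.03	-1.18	3.94E-08	**	Down
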