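ancestor	df	t	p_bound	fdr	group	broodmare
ID1	5	5.0863	< 0.01	*	Affected	no
ID11	12	3.3826	< 0.01	*	Affected	no
ID4	1	151.7273	< 0.01	*	Affected	no
ID8	12	4.354	< 0.001	*	Affected	no
ID2	9	3.0727	< 0.02	*	Affected	no
ID15	11	3.1227	< 0.01	*	Affected	no
ID26	3	3.7823	< 0.05	#	Affected	no
ID32	3	14.4752	< 0.001	*	Affected	yes
ID33	4	3.0569	< 0.05	#	Affected	no
ID34	4	3.3738	< 0.05	#	Affected	yes
ID35	8	4.6647	< 0.002	*	Affected	no
ID7	12	-9.4784	< 0.001	*	Control	no
ID9	12	-7.3222	< 0.001	*	Control	no
ID12	12	-7.3755	< 0.001	*	Control	no
ID17	12	-7.2343	< 0.001	*	Control	no
ID19	12	-6.4782	< 0.001	*	Control	no
ID20	12	-4.1063	< 0.002	*	Control	no
ID23	12	-6.0075	< 0.001	*	Control	no
ID28	12	-7.024	< 0.001	*	Control	no
ID29	12	-7.1564	< 0.001	*	Control	no
ID30	12	-4.2141	< 0.002	*	Control	no
ID38	10	-4.2976	< 0.002	*	Control	no
ID41	12	-17.475	< 0.001	*	Control	yes
ID37	12	-7.0793	< 0.001	*	Control	no
ID40	12	-11.2122	< 0.001	*	Control	yes
ID39	12	-17.6036	< 0.001	*	Control	yes
ID14	5	1.9418	N.S.		-	no
ID21	12	-1.209	N.S.		-	no
ID6	12	-1.372	N.S.		-	no
ID10	12	-1.9819	N.S.		-	no
ID13	12	-1.3826	N.S.		-	yes
ID3	4	2.5778	N.S.		-	no
ID16	12	1.3197	N.S.		-	no
ID18	12	-1.6611	N.S.		-	no
ID5	4	2.4813	N.S.		-	no
ID22	2	1.2627	N.S.		-	no
ID24	4	2.5977	N.S.		-	no
ID25	2	3.0586	N.S.		-	no
ID27	12	0.5217	N.S.		-	yes
ID31	12	-0.3303	N.S.		-	yes
ID36	12	1.7789	N.S.		-	yes
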