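ancestor	93/95	94/96	95/97	96/98	97/99	98/00	99/01	00/02	01/03	02/04	03/05	04/06	05/07	ave
ID1	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID11	0.125	0.036	0.035	0.032	0.032	0.032	0.032	0.034	0.031	0.031	0.026	0.029	0.023	0.038
ID14	0.086	-	-	-	-	-	-	-	-	-	-	-	-	0.086
ID4	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID21	0.035	0.108	0.110	0.104	0.108	0.105	0.111	0.111	0.107	0.104	0.100	0.097	0.093	0.099
ID6	0.075	0.087	0.088	0.087	0.087	0.085	0.085	0.085	0.086	0.085	0.086	0.087	0.088	0.085
ID7	0.104	0.121	0.121	0.122	0.120	0.121	0.120	0.119	0.121	0.122	0.125	0.126	0.127	0.121
ID8	0.014	0.013	0.011	0.011	0.011	0.025	0.030	0.043	0.043	0.042	0.041	0.041	0.045	0.028
ID9	0.079	0.094	0.094	0.095	0.093	0.094	0.095	0.093	0.094	0.094	0.097	0.099	0.101	0.094
ID10	0.062	0.075	0.075	0.074	0.074	0.073	0.071	0.073	0.070	0.069	0.068	0.065	0.064	0.070
ID2	-	-	-	-	-	0.003	-	-	-	-	-	-	-	0.003
ID12	0.046	0.053	0.053	0.053	0.052	0.052	0.052	0.052	0.053	0.053	0.053	0.053	0.053	0.052
ID13	0.001	0.034	0.034	0.033	0.035	0.033	0.035	0.031	0.030	0.030	0.029	0.027	0.026	0.029
ID3	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID15	-	-	0.013	0.021	0.027	0.024	-	-	0.017	0.020	0.018	0.019	-	0.020
ID16	0.008	0.004	0.006	0.006	0.008	0.003	0.012	0.012	0.014	0.014	0.015	0.013	0.012	0.010
ID17	0.026	0.028	0.027	0.028	0.026	0.028	0.026	0.025	0.026	0.026	0.030	0.025	0.028	0.027
ID18	0.028	0.030	0.030	0.031	0.029	0.013	0.013	0.013	0.013	0.013	0.013	0.012	0.028	0.020
ID19	0.017	0.019	0.018	0.019	0.018	0.029	0.029	0.028	0.030	0.031	0.033	0.026	0.014	0.024
ID20	0.022	0.020	0.020	0.019	0.019	0.016	0.019	0.019	0.020	0.019	0.020	0.019	0.017	0.019
ID5	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID22	-	-	-	-	-	0.009	-	-	-	-	-	-	-	0.009
ID23	0.010	0.012	0.014	0.016	0.014	0.012	0.012	0.012	0.014	0.014	0.015	0.016	0.020	0.014
ID24	-	-	-	-	-	-	0.006	-	-	-	-	-	-	0.006
ID25	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID26	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID27	0.007	0.007	0.007	0.007	0.007	0.007	0.007	0.006	0.006	0.006	0.006	-	0.006	0.007
ID28	0.013	0.016	0.017	0.019	0.018	0.020	0.018	0.018	0.021	0.023	0.025	0.025	0.023	0.020
ID29	0.018	0.017	0.017	0.014	0.014	0.013	0.011	0.011	0.011	0.011	0.011	0.010	0.013	0.013
ID30	0.013	0.015	0.010	0.012	0.011	0.019	0.020	0.019	0.020	0.021	0.023	0.034	0.036	0.019
ID31	0.006	0.007	0.007	0.007	0.006	0.007	-	0.007	0.006	0.006	0.005	0.005	0.004	0.006
ID32	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID33	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID34	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID35	-	-	-	-	-	-	-	-	-	-	-	-	-	-
ID36	0.002	0.002	0.002	0.002	0.002	0.001	0.001	0.001	0.001	0.001	0.001	0.002	0.001	0.001
ID38	0.011	0.010	0.003	0.004	0.005	0.004	0.020	0.018	0.005	0.004	-	0.006	-	0.008
ID41	0.007	0.008	0.008	0.008	0.008	0.007	0.007	0.007	0.008	0.008	0.008	0.009	0.009	0.008
ID37	0.007	0.008	0.008	0.008	0.008	0.007	0.007	0.007	0.007	0.007	0.008	0.008	0.008	0.007
ID40	0.007	0.008	0.008	0.008	0.008	0.007	0.007	0.007	0.007	0.007	0.007	0.007	0.007	0.007
ID39	0.004	0.005	0.005	0.006	0.005	0.005	0.005	0.005	0.005	0.004	0.005	0.006	0.006	0.005
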