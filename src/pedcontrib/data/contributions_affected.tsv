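ancestor	93/95	94/96	95/97	96/98	97/99	98/00	99/01	00/02	01/03	02/04	03/05	04/06	05/07	ave
ID1	-	-	-	-	-	-	-	0.010	0.174	0.200	0.205	0.148	0.158	0.149
ID11	0.038	0.128	0.142	0.147	0.144	0.141	0.099	0.101	0.028	0.030	0.026	0.119	0.110	0.096
ID14	-	0.094	-	0.095	0.100	-	-	-	-	-	-	0.066	0.071	0.085
ID4	-	-	0.083	-	-	-	-	0.084	-	-	-	-	-	0.083
ID21	0.127	0.047	0.086	0.038	0.046	0.094	0.141	0.142	0.115	0.093	0.088	0.033	0.035	0.083
ID6	0.116	0.102	0.057	0.099	0.090	0.085	0.051	0.039	0.066	0.075	0.074	0.067	0.075	0.077
ID7	0.084	0.069	0.100	0.066	0.064	0.061	0.080	0.070	0.089	0.055	0.054	0.043	0.051	0.068
ID8	0.032	0.042	0.047	0.036	0.041	0.106	0.129	0.122	0.045	0.043	0.044	0.093	0.092	0.067
ID9	0.087	0.076	0.068	0.070	0.069	0.059	0.051	0.049	0.067	0.055	0.053	0.048	0.057	0.062
ID10	0.088	0.076	0.019	0.074	0.072	0.067	0.051	0.017	0.074	0.062	0.058	0.045	0.049	0.058
ID2	0.019	0.021	-	-	-	-	0.022	0.024	0.044	0.117	0.128	0.081	0.006	0.051
ID12	0.050	0.036	0.041	0.042	0.035	0.033	0.028	0.027	0.033	0.021	0.030	0.024	0.028	0.033
ID13	0.038	-	0.031	0.000	-	0.042	0.036	0.041	0.027	0.032	0.023	-	-	0.030
ID3	-	-	0.016	0.011	0.016	0.025	0.069	-	-	-	-	-	-	0.027
ID15	0.026	0.007	0.017	0.019	0.026	0.020	-	0.017	0.023	0.027	0.026	0.029	0.031	0.022
ID16	0.019	0.023	0.005	-	-	-	0.004	0.056	0.018	0.012	0.014	0.019	0.024	0.019
ID17	0.023	0.024	0.024	0.019	0.022	0.015	0.012	0.016	0.014	0.013	0.013	0.016	0.020	0.018
ID18	0.024	0.025	0.010	0.021	0.020	0.015	0.012	0.015	0.016	0.015	0.015	0.017	0.019	0.017
ID19	-	-	0.025	-	-	-	-	0.008	-	-	-	-	0.012	0.015
ID20	0.013	0.012	0.017	0.017	0.022	0.016	0.013	0.017	0.011	0.011	0.010	0.014	0.016	0.015
ID5	0.002	-	0.002	0.026	0.012	0.026	-	-	-	-	-	-	-	0.013
ID22	-	-	-	0.001	-	0.012	0.025	-	-	-	-	-	-	0.012
ID23	-	0.009	0.013	0.010	0.015	-	-	-	-	-	-	-	-	0.012
ID24	0.005	-	-	-	0.016	0.019	-	0.006	0.007	-	-	-	-	0.011
ID25	-	0.007	0.006	-	-	-	0.017	-	-	-	-	-	-	0.010
ID26	0.017	-	-	-	-	-	-	-	0.007	0.006	-	-	0.009	0.009
ID27	0.012	0.012	0.003	0.012	0.009	0.006	-	-	0.009	0.008	0.008	0.010	-	0.009
ID28	0.011	0.010	0.012	0.008	0.007	-	-	0.007	0.007	0.005	-	-	0.010	0.008
ID29	0.010	0.011	0.008	0.007	0.009	0.006	-	0.007	0.008	0.008	0.008	-	-	0.008
ID30	0.009	0.016	0.008	0.007	0.007	0.009	-	0.010	0.004	-	0.002	-	-	0.008
ID31	-	0.001	0.009	0.013	0.004	0.004	0.005	-	-	0.006	0.006	0.009	0.009	0.007
ID32	0.006	-	-	-	0.005	0.007	0.007	-	-	-	-	-	-	0.006
ID33	0.003	0.003	0.011	0.009	0.002	-	-	-	-	-	-	-	-	0.006
ID34	0.008	0.009	0.001	-	-	-	-	0.008	-	-	0.002	-	-	0.006
ID35	0.002	0.002	-	0.007	0.010	0.010	0.009	0.005	0.003	0.002	-	-	-	0.005
ID36	0.007	0.006	-	0.006	0.005	-	-	-	0.005	0.005	0.003	-	-	0.005
ID37	0.005	-	0.005	0.005	0.004	-	-	0.004	0.005	0.005	-	-	-	0.005
ID38	-	-	0.001	0.002	0.002	0.002	0.013	-	-	-	-	-	-	0.004
ID39	-	-	0.003	-	-	-	-	-	-	-	-	-	-	0.003
ID40	0.006	-	0.004	0.003	-	-	-	-	0.002	0.000	-	-	-	0.003
ID41	-	-	0.005	-	-	-	-	-	-	0.000	-	-	-	0.003
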