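mirna	B1	B2	Q2	Q1	T1	T2	log2fc	pvalue	fdr
sof-miRN167-3p	0	0	0	14.33	10.177	0	8.451	5.50E-17	5.01E-15
sof-miR167b-5p	23.223	0.595	11.448	807.81	63.317	135.635	4.471	6.69E-25	1.83E-22
sof-miR167c-5p	24.996	1.444	9.526	822.728	64.377	130.387	4.433	1.50E-24	2.15E-22
sof-miR167a-5p	24.996	1.444	9.526	821.722	64.2	129.853	4.430	1.57E-24	2.15E-22
sof-miR408-3p	0.422	0.17	0.836	18.186	5.387	11.562	4.126	2.64E-16	2.06E-14
sof-miR167b-3p	2.027	0.085	1.421	21.79	6.535	43.759	4.042	5.59E-19	6.12E-17
sof-miR167a-3p	3.378	1.019	0.251	30.673	6.358	28.372	3.355	4.40E-14	2.19E-12
sof-miR156-5p	34.454	15.712	60.251	288.775	76.917	230.445	3.317	5.85E-16	4.00E-14
sof-miR396b-5p	654.118	30.491	108.299	6328.725	927.242	1603.601	3.166	6.63E-15	4.01E-13
sof-miR396a-5p	655.3	30.491	108.968	6310.874	927.153	1603.868	3.160	7.32E-15	4.01E-13
sof-miR396c-3p	3.124	0	1.172	5.812	4.857	6.848	2.721	2.06E-10	8.68E-09
sof-miRN375-3p	3.124	0	1.172	5.812	4.857	6.848	2.721	2.06E-10	8.68E-09
sof-miR395c-5p	1.942	0.934	1.671	5.615	9.184	12.541	2.178	6.80E-07	1.62E-05
sof-miR395a-3p	1.942	1.104	1.671	5.615	9.184	12.541	2.106	1.68E-06	3.84E-05
sof-miR395b-5p	1.942	1.104	1.671	5.447	8.036	12.541	2.036	3.71E-06	7.51E-05
sof-miR156-3p	0.338	0.51	0.585	5.783	1.06	0.889	1.816	0.001132	0.009671
sof-miRN145-3p	1.351	0.595	0.084	0.084	9.449	0.089	1.807	0.000279	0.003154
sof-miRN267-5p	2.364	0	0.752	7.878	2.561	3.38	1.765	4.95E-05	0.000714
sof-miR5384-3p	1.52	0	0.836	9.638	0	1.067	1.693	0.000205	0.002547
sof-miRN054-3p	19	14.014	8.022	115.904	19.516	63.771	1.634	3.06E-05	0.000507
sof-miR171c-3p	25.165	0.679	2.507	80.119	6.8	8.005	1.378	0.000357	0.003909
sof-miR166d-5p	4.222	1.274	3.51	20.533	3.797	7.649	1.352	0.001059	0.009198
sof-miR393-3p	9.289	3.142	5.933	30.17	10.509	21.079	1.306	0.001004	0.009006
sof-miR393-5p	45.516	11.975	24.651	150.433	31.261	83.426	1.261	0.000992	0.009006
sof-miRN014-3p	0	0.425	3.844	6.788	6.711	0.356	1.219	0.006096	0.040176
sof-miRN164-5p	14.187	7.134	8.189	0	5.652	9.872	-1.307	0.001391	0.011189
sof-miRN060-3p	8.445	9.682	8.858	5.531	4.592	4.091	-1.543	0.000147	0.001867
sof-miRN141-3p	33.272	1.529	18.551	0	0	18.411	-1.631	5.92E-05	0.00083
sof-miRN097-5p	45.094	23.866	23.147	24.639	7.948	10.05	-1.678	1.79E-05	0.000326
sof-miR166e-5p	31.583	5.606	17.465	1.257	7.241	10.94	-1.728	1.86E-05	0.000328
sof-miRN003-5p	5.236	0.085	0.501	0.251	0.177	1.512	-1.814	0.001153	0.009704
sof-miRN377-5p	1.013	10.277	0.836	1.341	2.384	1.779	-2.094	1.86E-06	4.08E-05
sof-miR166g-5p	56.325	17.241	59.498	2.179	9.537	25.437	-2.103	1.23E-07	3.53E-06
sof-miR159-5p	7.61	4.863	24.651	10.392	0.442	6.226	-2.106	1.93E-07	5.02E-06
sof-miRN207-5p	7.093	15.797	15.961	5.28	3.444	3.113	-2.406	6.38E-09	2.33E-07
sof-miRN245-5p	0.084	7.134	1.086	0.503	0.883	1.334	-2.529	1.64E-07	4.50E-06
sof-miRN303-5p	1.013	11.975	0.084	0.587	2.384	1.512	-2.534	2.08E-08	7.10E-07
sof-miR319-3p	404.581	660.938	5.766	163.842	1.325	1.512	-4.864	1.95E-28	1.07E-25
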