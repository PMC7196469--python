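rsid	ea	eaf	beta_exp	se_exp	pval_exp	beta_out	se_out	pval_out
rs10132280	A	0.282	-0.022	0.004	1.10e-09	0.012	0.011	0.254
rs10786712	C	0.598	-0.018	0.003	4.10e-08	0.043	0.009	5.08e-06
rs10840100	G	0.608	0.019	0.003	1.20e-08	0.015	0.010	0.125
rs10938397	A	0.584	-0.032	0.003	5.60e-22	-0.031	0.009	0.001
rs11039290	A	0.308	-0.022	0.004	1.50e-09	-0.004	0.010	0.724
rs11165623	A	0.464	0.021	0.003	3.90e-10	0.008	0.009	0.415
rs11676272	G	0.474	0.021	0.004	5.20e-09	0.020	0.009	0.028
rs13404250	C	0.679	0.021	0.004	1.60e-09	0.026	0.010	0.011
rs1412235	C	0.293	0.024	0.004	6.90e-12	0.023	0.010	0.025
rs1421085	C	0.380	0.072	0.003	1.30e-102	0.030	0.010	0.002
rs1519480	C	0.350	0.03	0.004	2.90e-18	0.024	0.010	0.016
rs16996700	T	0.741	0.022	0.004	4.90e-10	0.004	0.011	0.722
rs17066856	C	0.105	-0.035	0.006	1.90e-10	-0.038	0.015	0.015
rs17381664	C	0.349	0.022	0.004	4.00e-10	0.016	0.010	0.113
rs17724992	A	0.706	0.021	0.004	2.40e-08	0.014	0.010	0.174
rs1928295	C	0.437	-0.018	0.003	1.70e-08	-0.007	0.010	0.469
rs2033529	G	0.266	0.02	0.004	1.80e-08	-0.006	0.010	0.547
rs2278076	A	0.240	-0.024	0.004	2.50e-09	-0.013	0.011	0.220
rs2287019	C	0.817	0.033	0.004	4.70e-14	0.039	0.013	0.002
rs2307111	C	0.443	-0.025	0.003	1.10e-13	-0.008	0.010	0.429
rs2325036	A	0.587	0.021	0.003	1.10e-10	0.001	0.009	0.879
rs2357760	A	0.651	0.019	0.003	4.10e-08	0.017	0.010	0.088
rs2531992	A	0.215	-0.027	0.005	2.70e-09	0.004	0.012	0.768
rs2867110	C	0.167	-0.051	0.004	2.30e-32	-0.040	0.012	0.001
rs3127553	G	0.402	0.022	0.003	5.20e-11	0.010	0.010	0.281
rs3800229	T	0.653	0.023	0.004	5.60e-11	0.004	0.010	0.694
rs4234589	G	0.127	-0.032	0.005	9.60e-11	-0.011	0.014	0.412
rs4788099	G	0.346	0.034	0.003	2.00e-24	0.016	0.010	0.112
rs4883723	G	0.834	-0.028	0.005	1.30e-09	-0.007	0.013	0.580
rs4985155	A	0.640	0.019	0.003	3.00e-08	-0.006	0.010	0.500
rs543874	G	0.189	0.044	0.004	2.00e-26	0.008	0.012	0.517
rs6440003	G	0.579	-0.021	0.003	9.10e-11	0.017	0.010	0.072
rs6545714	G	0.386	0.022	0.003	5.40e-11	0.010	0.010	0.288
rs6567160	C	0.254	0.05	0.004	5.80e-38	0.058	0.011	4.56e-08
rs6864049	A	0.445	-0.019	0.003	2.40e-08	-0.004	0.010	0.671
rs7138803	G	0.628	-0.028	0.003	1.60e-16	-0.008	0.010	0.388
rs7144011	T	0.202	0.032	0.004	1.60e-15	0.021	0.012	0.076
rs7239883	G	0.388	0.019	0.003	5.90e-09	0.002	0.010	0.866
rs749671	A	0.361	-0.02	0.003	4.80e-09	-0.010	0.010	0.308
rs7531118	T	0.519	-0.027	0.003	5.40e-15	-0.018	0.010	0.069
rs7550711	T	0.028	0.057	0.010	3.10e-09	-0.048	0.031	0.114
rs7649970	T	0.125	0.027	0.005	1.90e-08	-0.001	0.014	0.969
rs7903146	T	0.276	-0.022	0.004	1.70e-09	0.033	0.010	0.001
rs806794	G	0.330	-0.022	0.004	1.50e-09	-0.013	0.010	0.185
rs929641	A	0.573	0.019	0.003	7.70e-09	0.015	0.010	0.122
rs943005	T	0.182	0.039	0.004	7.00e-20	0.018	0.012	0.130
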