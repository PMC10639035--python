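# SYNTHETIC 38-index dinucleotide property table (deterministic stand-in).
# Not a published compilation: values are seeded standard-normal draws, used to
# exercise the 38-index parallel-correlation encoder at full width. Replace with
# your own TSV of real physicochemical indices for production use.
index	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
SYN01	0.4547	0.9554	-0.9376	-0.3043	0.8887	0.9253	-0.4321	1.827	0.1821	1.1964	-0.5611	-0.6559	0.7145	-0.034	0.5603	-0.3044
SYN02	0.2312	-0.8571	-2.2746	-0.5151	0.6045	0.4946	0.0681	-0.8323	0.6013	1.0893	-0.2992	-0.5599	0.3635	-1.0897	2.011	0.2986
SYN03	1.1794	-0.9414	-0.3877	1.327	-0.0014	0.5412	0.6668	-1.7815	1.334	-0.8187	-0.7063	0.7163	-0.669	2.1304	-0.275	-1.5369
SYN04	-0.8424	0.5502	1.1009	-0.1159	-0.4446	0.2736	0.9995	1.3303	-0.4595	-0.9594	-0.3422	-2.5086	-0.2384	0.1647	-1.6245	1.4758
SYN05	0.0861	-0.4972	-0.1718	-0.3784	0.5651	-0.1537	0.2406	-0.1541	0.5913	-0.4784	1.0168	-0.3177	0.2211	0.938	-0.4321	0.2576
SYN06	-0.4207	1.9309	2.0193	0.1771	0.685	-0.7735	0.7501	0.1508	-0.6823	-0.1657	0.6393	-1.344	0.288	1.0844	-0.1623	1.029
SYN07	0.0272	0.2149	-1.4827	-1.2652	-0.0489	-1.3	0.4892	0.6435	1.8393	0.2209	1.5758	0.0562	-1.6192	0.0656	-1.5948	0.1535
SYN08	-0.5931	-1.4021	1.2317	0.8993	-0.5214	-0.3183	-0.1684	-1.3029	-1.1584	0.1523	1.1732	-0.8535	1.0582	0.6263	-0.9134	-0.8805
SYN09	-0.2592	1.7125	0.0181	0.1432	1.5088	0.6053	1.0733	-1.1676	-0.9011	2.1312	1.7891	0.0386	0.0106	-1.1035	1.3853	1.4409
SYN10	-0.8913	0.8583	0.3881	-0.3433	-1.0989	1.0592	0.8709	-0.8793	0.892	1.033	-2.4175	-2.1647	1.7625	-0.385	0.0785	0.9874
SYN11	0.0479	-0.2268	-0.4626	-1.2351	0.0116	-1.0147	0.3761	0.3006	-2.2705	0.4151	0.7383	0.778	0.2943	1.2983	-2.5272	0.3046
SYN12	-1.1112	-1.6098	0.5739	-0.5861	-1.714	-0.7583	0.4787	-0.2956	1.0023	-0.0098	0.3228	-0.1712	0.5793	-0.7221	1.842	2.0519
SYN13	1.3136	1.1854	1.5525	1.5143	1.0799	0.7582	0.2269	0.0015	0.3842	-0.5285	-0.3742	-0.3503	0.894	-1.0616	0.2264	-0.1876
SYN14	0.4446	1.7227	-0.76	-0.4474	1.1057	-0.0639	-0.1039	1.6947	-0.5875	0.5846	0.803	0.5709	2.1901	0.2597	0.2449	1.1322
SYN15	-0.9161	0.3915	-0.1296	1.2854	0.5501	-0.6834	-0.6865	2.7805	1.5451	0.0829	2.8665	-0.4268	-1.4143	1.267	0.2002	0.2239
SYN16	-0.6181	0.2937	1.4832	0.4624	-1.5358	1.7406	0.7496	-1.1962	0.2288	-0.5531	-0.777	-1.3049	0.9432	1.7048	0.1004	-0.0047
SYN17	0.4311	0.3894	-0.6497	-1.6012	-0.6511	-0.0439	-0.3187	-0.1695	-1.7891	-1.8566	0.8516	0.0419	-0.9601	0.8001	-1.1888	1.2538
SYN18	0.7979	-0.9031	-0.9355	-1.0598	0.4273	0.6352	2.1808	-0.2101	-0.7842	0.2703	-0.0311	1.8669	-0.6184	0.4448	-2.2053	1.2477
SYN19	0.2575	-0.4131	-1.4261	0.5748	1.0547	0.834	-1.8386	-0.5197	-0.1412	1.0661	-0.7616	-3.0095	0.0595	-0.1124	-1.0428	0.2974
SYN20	-0.5467	1.728	1.4433	3.1659	-0.0096	0.6542	1.8883	1.358	-0.1217	-0.0887	-0.2478	-0.0362	1.0456	-0.5922	-1.3303	-1.5275
SYN21	-0.5894	1.1492	0.9515	-1.4643	0.3541	0.3276	-0.5885	0.1746	-1.719	0.2845	0.708	-0.6414	0.339	-0.4778	-0.3788	-0.1113
SYN22	0.4267	-0.9739	0.3892	-1.8066	-1.8133	1.4909	0.163	-0.9152	-0.2512	-0.2078	-0.4833	-0.4963	0.0228	-0.0813	-1.5702	-0.6062
SYN23	1.2748	-0.6098	-0.5372	0.8696	1.6318	-1.5233	1.0932	1.9307	-1.6613	1.0584	-0.6687	-0.3903	1.456	2.7782	1.0796	1.2096
SYN24	-0.3318	0.4262	-0.4948	1.2827	-1.1395	-0.8181	-0.4421	-0.0013	-0.0271	-0.1622	1.9918	-0.6366	0.4933	-0.5954	1.6949	0.0659
SYN25	2.0116	-0.2372	-0.5936	-0.1758	0.0018	2.5365	-2.2034	0.2545	-1.7202	0.4219	0.7497	0.2889	0.085	-0.6824	-0.8052	0.4938
SYN26	-1.2635	-1.5954	-0.6613	-1.6842	0.2174	-0.8282	0.3032	-0.8342	0.6911	0.6712	0.1293	0.7063	0.1609	0.9283	-0.8734	-0.926
SYN27	-0.5617	0.2202	-0.9933	-0.5182	-0.3203	-0.4381	0.7297	-0.8834	1.0953	-0.1542	0.1735	1.3774	0.966	-1.4754	0.6615	0.5477
SYN28	-1.0982	0.6526	-0.5472	-0.8079	-0.8294	-0.436	-1.0185	-0.6091	-1.4466	-0.8071	0.6773	-0.108	0.9123	1.184	1.4483	0.1112
SYN29	-0.9571	-0.2133	1.4901	1.1922	-0.5251	-0.2182	1.361	1.1862	0.5573	-0.129	-0.3072	0.6252	1.2036	-0.0808	-0.5099	-0.3076
SYN30	-0.4143	-0.4696	0.411	-0.4614	-0.4036	-1.5894	-0.212	-0.5547	-0.9655	0.4993	1.1201	-1.2891	1.1323	-0.8329	-0.3262	-0.7895
SYN31	-1.0965	-2.2467	0.2113	-1.3782	0.0759	1.4802	-0.3177	0.6497	-0.2736	0.3088	-0.7192	0.3543	0.989	2.624	0.5525	1.5867
SYN32	-0.6564	0.8069	-1.335	0.4209	0.0093	0.4251	1.3541	0.1561	0.4408	0.6914	-0.7829	-1.1754	1.5624	1.3331	-0.3134	-0.2694
SYN33	-0.292	-0.4337	-0.1755	-0.0496	-1.448	-2.6829	1.0108	-0.2946	-1.1017	0.0613	0.6639	1.701	-2.2719	-0.3864	0.2547	0.7962
SYN34	0.2686	-0.1361	-0.8357	-2.0822	-1.9446	-1.0329	0.0831	-1.3969	-0.1795	-0.3838	-0.1554	-0.8666	0.0658	0.5162	1.8575	0.7571
SYN35	0.2903	1.0049	-0.7955	-0.476	-1.6139	0.2109	-0.0122	0.5288	-0.0454	-0.2082	-0.2016	-0.0362	-1.0191	-2.2017	-0.3887	-0.8105
SYN36	-0.7012	-0.0271	-1.0007	-0.2821	-1.1973	-3.021	0.6003	0.0594	-0.6103	-0.6294	-1.7574	0.4271	0.0904	-0.3295	0.2479	0.1189
SYN37	1.4595	-0.5357	1.4622	-1.2165	-1.6135	-0.7576	0.6368	1.1477	0.5173	0.0229	0.2331	-0.2642	-0.5576	-0.5739	0.2291	-0.8039
SYN38	1.2389	-0.3804	-0.1994	-0.5244	0.096	-0.4891	0.971	-0.1629	0.6579	0.3322	-0.8695	-1.1755	-1.6559	0.8688	0.5861	-0.2139
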