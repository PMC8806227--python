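gene	CellTypeA	CellTypeB	CellTypeC	CellTypeD	CellTypeE	CellTypeF
MKR000	13.9262	1.8458	1.6635	0.8378	0.9502	1.8103
MKR001	9.799	1.7318	1.6956	1.2019	0.9545	0.9176
MKR002	14.1988	1.1676	1.2568	1.3302	1.9933	1.689
MKR003	14.7371	1.9834	0.823	0.7403	1.4188	0.5659
MKR004	13.6026	1.2723	1.1993	1.8758	1.4438	1.2712
MKR005	12.3589	0.8713	0.5177	0.7886	1.538	0.8009
MKR006	11.7016	0.5056	1.7451	0.7317	0.9014	1.8205
MKR007	12.2031	1.7707	1.4596	1.6127	0.6372	1.3117
MKR008	1.2617	10.0404	1.0419	1.3973	0.5889	1.0814
MKR009	0.9846	14.6355	1.7245	1.0692	1.9681	1.385
MKR010	1.4076	13.2536	1.5147	0.7262	1.1605	0.8593
MKR011	1.1037	11.3577	1.9517	0.8225	1.5076	0.9506
MKR012	1.8111	13.3295	0.6974	1.7676	1.9174	1.8559
MKR013	1.3546	13.7697	0.7887	1.8919	1.3285	0.7708
MKR014	1.8261	12.1326	1.3545	1.0644	1.1164	0.8592
MKR015	0.5571	15.6288	1.2016	1.3215	0.9832	1.627
MKR016	0.5378	1.0583	14.9818	0.6843	1.9507	1.4866
MKR017	1.1423	1.2856	12.5212	1.0163	1.3854	1.5255
MKR018	1.0331	1.2786	10.6126	1.8638	0.7266	1.9001
MKR019	0.5078	1.6295	15.0384	0.7051	1.1284	1.7229
MKR020	0.5214	1.4427	16.6402	1.2695	1.5888	0.8396
MKR021	0.7978	1.0447	9.805	1.0191	1.9222	1.36
MKR022	1.0101	0.9073	14.9168	1.1667	1.9706	1.2733
MKR023	1.2817	1.8448	15.3914	1.371	1.14	1.8173
MKR024	1.1175	1.8841	0.6031	15.589	1.2793	1.9264
MKR025	0.8765	1.7091	1.5147	10.4393	1.4444	1.9573
MKR026	0.999	1.0974	0.8044	9.2187	0.8194	1.8732
MKR027	1.7603	0.6686	1.4057	16.1339	1.392	1.4889
MKR028	0.96	1.942	1.1988	10.2594	1.4528	0.7758
MKR029	0.5928	1.1173	1.646	10.9605	1.595	0.6698
MKR030	1.87	1.7031	1.8165	13.3096	1.8735	0.57
MKR031	0.5454	0.5303	0.8792	11.9968	0.7813	1.3506
MKR032	0.5585	1.3856	0.749	1.5168	13.7844	0.9659
MKR033	1.9075	1.3076	1.7174	1.487	10.75	0.7869
MKR034	1.3616	0.5595	1.7025	1.9401	16.182	0.5761
MKR035	1.008	0.977	0.6691	1.4399	11.2166	0.9706
MKR036	1.7942	1.6957	0.6937	1.6503	15.2077	0.7959
MKR037	1.3605	1.4581	1.414	0.6444	9.965	1.4479
MKR038	1.7358	1.7053	0.9908	1.5831	13.1147	1.8394
MKR039	0.7423	0.5401	1.4762	0.822	9.5735	1.9172
MKR040	1.069	0.8792	1.1848	1.4859	0.6516	11.2676
MKR041	0.7006	1.4937	1.7458	1.0653	1.0576	11.4949
MKR042	0.8226	0.8711	0.9948	1.1861	0.6223	14.6673
MKR043	1.3686	0.9495	0.6163	1.6448	0.6966	11.8849
MKR044	0.696	0.6219	1.8596	0.9039	0.9596	10.1466
MKR045	1.4299	0.7807	1.1522	1.8259	1.0631	16.5339
MKR046	0.6452	1.591	1.6647	1.7387	1.5113	15.277
MKR047	0.5963	1.2782	1.6362	0.7863	0.8994	15.7184
MKR048	1.6225	1.8449	0.6886	0.7764	1.6993	1.4668
MKR049	1.5815	1.9952	1.9088	1.7645	1.6657	1.0925
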