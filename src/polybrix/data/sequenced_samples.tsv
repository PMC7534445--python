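program	name	mean_ssc_brix	ccs_reads	mean_ccs_len	median_ccs_len	hv1_group	rov3_group
HCRU	ORUS 4647M	7.6	10745	2678.00	2767	1	3
HCRU	ORUS 4540N	8.0	17995	2723.20	2720	1	3
HCRU	ORUS 4647L	8.2	62	1628.70	1493.5	2	2
HCRU	ORUS 4647R	8.6	32015	2880.20	2936	1	3
HCRU	ORUS 4647U	8.9	6914	1802.90	1561	1	3
HCRU	Kotata	9.3	4310	1109.10	1029	1	4
HCRU	Bassettberry	9.7	5185	1924.70	1646	1	3
HCRU	Ollalie	9.7	1640	1118.00	1067	2	4
HCRU	Silvan	9.7	9542	3116.70	3603	1	3
HCRU	Black Diamond	10.5	4509	2492.60	2369	1	3
HCRU	ORUS 1932-1	11.5	9484	2963.70	3258	1	3
HCRU	Marion	12.2	5707	1173.30	1095	1	4
HCRU	Nightfall	12.2	9522	2676.80	2439	3	3
HCRU	Columbia Star	12.8	3988	2703.30	2689.5	1	3
HCRU	Waldo	13.7	6397	2478.10	2143	1	3
HCRU	ORUS 4540A	15.1	4761	2038.20	1702	3	1
HCRU	ORUS 4540I	15.6	16413	3108.20	3386	1	3
HCRU	ORUS 4674C	16.3	2840	1085.90	973.5	1	4
HCRU	ORUS 4674J	17.1	2289	1119.00	1017	1	4
HCRU	ORUS 4660T	18.4	7681	2320.20	2208	3	3
UA	Choctaw	7.4	130	1662.60	1464	2	2
UA	Comanche	7.5	22542	3465.50	3758	3	1
UA	A-2562T	8.3	28239	2112.40	1888	1	1
UA	APF-329	8.4	9420	2947.00	3009.5	3	1
UA	A-2418T	8.6	22640	2878.10	2942	1	1
UA	APF-326TN	8.6	122	1218.30	1152.5	2	2
UA	Cheyenne	8.6	4332	1061.60	977.5	2	4
UA	APF-236T	8.7	37369	3062.30	3125	3	1
UA	APF-306T	8.7	6833	2741.90	2679	3	1
UA	Kiowa	9.0	13368	2425.60	2200	3	1
UA	A-2421	11.6	3260	1140.70	1050	1	4
UA	A-2548T	11.7	2984	1148.80	1054	1	4
UA	Osage	11.7	32607	3432.50	3681	3	1
UA	A-2444T	11.9	27512	2359.00	2081	3	1
UA	A-2552T	12.0	14495	2918.80	2960	1	1
UA	Ponca	12.2	2904	877.5	789	2	4
UA	A-2542T	12.2	23180	2967.50	3005	1	1
UA	A-2496	12.3	7112	1815.00	1555	1	1
UA	A-2487T	12.4	5154	2831.80	2876	3	1
UA	APF-318	14.3	3965	1789.20	1602	1	1
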