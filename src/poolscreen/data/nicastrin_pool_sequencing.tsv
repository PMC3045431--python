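position	ref	alt	aa_change	case_freq	case_depth	case_fr_score	control_freq	control_depth	control_fr_score	genotyped_case_freq	genotyped_case_n	genotyped_control_freq	genotyped_control_n	below_cutoff
158579744	T	G		0.011	43865	0.06	0.012	53337	0.35	0.000	290	0.000	343	False
158579822	A	G	4A>A	0.008	29914	0.75	0	37900					False
158579842	A	G	11D>G	0.034	32766	1.09	0.033	40522	1.05	0.000	290	0.000	342	False
158585459	G	A	79E>E	0.015	49008	0.41	0	77896					False
158585487	G	T	89G>C	0.009	62187	0.10	0.009	96747	0.10	0.000	290	0.000	345	True
158587689	A	G	212L>L	0.038	68900	0.10	0.054	72522	0.19					False
158588079	G	A		0.006	24984	0.54	0	59781					False
158588123	C	T	249D>D	0.033	28255	0.32	0.054	67365	0.40	0.035	276	0.048	344	False
158588214	A	T	280T>S	0.006	23823	1.68	0.006	54929	0.14	0.000	282	0.000	339	False
158588214	A	C	280T>P	0.093	23823	1.68	0.100	54929	0.14	0.002	280	0.000	341	False
158590601	A	T	417N>Y	0.012	33904	0.77	0	41705		0.019	287	0.004	345	False
158592193	T	G		0.016	49363	0.14	0.017	91556	0.22	0.002	288	0.000	345	False
158592559	T	C		0.013	61645	0.44	0.014	119627	0.42	0.000	290	0.000	343	False
158593669	T	G		0.009	51485	0.37	0	66754					False
158594855	G	C		0	61686		0.005	72880	0.42					False
158594885	A	C		0.014	51872	0.95	0	60335		0.000	290	0.000	343	False
158594972	G	T		0.042	49352	1.56	0.051	58461	1.62	0.000	288	0.001	345	True
158594975	A	C		0.026	47088	0.81	0.027	55505	0.83					False
158594975	A	T		0	47088		0.012	55505	1.29198185					False
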