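study	n_cases	n_controls	freq_case	freq_control	or	ci_lo	ci_hi	weight_pct
Greece	347	369	0.016	0.004	3.994	1.105	14.439	42.14
UK	421	593	0.007	0.004	1.700	0.515	5.608	48.86
Other Western Europeans	145	141	0.003	0.004	0.979	0.061	15.807	9.00
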