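variant	aa_change	group	n	hom_minor	het
158588123	D249D	case	276	0	20
158588123	D249D	control	344	1	31
158588214	T280P	case	280	0	1
158588214	T280P	control	341	0	0
158590601	N417Y	case	287	0	11
158590601	N417Y	control	345	0	3
158592193		case	288	0	1
158592193		control	345	0	0
158594972		case	288	0	0
158594972		control	345	0	1
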