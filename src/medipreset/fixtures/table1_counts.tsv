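comparison	direction	all_regions	HCP	ICP	LCP
mLP-CN vs mCN-CN	hyper	478	280	129	69
mLP-CN vs mCN-CN	hypo	576	264	152	160
mLP-CN vs mCN-CN	total	1054	544	281	229
mLP-LP vs mLP-CN	hyper	697	408	172	117
mLP-LP vs mLP-CN	hypo	405	188	124	93
mLP-LP vs mLP-CN	total	1102	596	296	210
mLP-HP vs mLP-CN	hyper	927	486	233	208
mLP-HP vs mLP-CN	hypo	366	162	107	97
mLP-HP vs mLP-CN	total	1293	648	340	305
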