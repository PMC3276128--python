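genotype	experiment_id	matched_control_id	normal	exc_female	exc_male	status	breakpoints
X/X;bubR1[D1326N]/bubR1[rev1]	10		737	102	34	ok	
Df(3L)rdgC-co2	10	10	686	37	11	ok	77A1;77D1
Df(3L)ED4858	10	10	566	23	13	ok	76D3;77C1
Df(3L)Exel6136	10	10	1996	9	5	ok	77B2;77C6
polo[1]/+	10	10	438	35	17	ok	
polo[2]/+	10	10	1612	32	25	ok	
polo[9]/+	10	10	979	36	21	ok	
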