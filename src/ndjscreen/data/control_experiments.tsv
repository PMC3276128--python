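genotype	experiment_id	matched_control_id	normal	exc_female	exc_male	status	breakpoints
X/X;bubR1[D1326N]/bubR1[rev1]	1		1869	122	64	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	2		2641	280	40	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	3		1452	149	48	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	4		2885	272	153	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	5		1782	233	33	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	6		1286	111	85	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	7		1138	157	28	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	8		972	130	32	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	9		1545	170	107	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	10		737	102	34	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	11		1324	178	72	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	12		282	45	10	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	13		631	79	49	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	14		1116	210	44	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	15		775	167	22	ok	
X/X;bubR1[D1326N]/bubR1[rev1]	16		681	166	19	ok	
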