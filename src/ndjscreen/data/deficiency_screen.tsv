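genotype	experiment_id	matched_control_id	normal	exc_female	exc_male	status	breakpoints
Df(3L)BSC23	2	2	550	127	16	ok	62E8;63B5-6
Df(3L)BSC13	5	5	841	281	14	ok	66B12-C1;66D2-4
Df(3L)Pc-2q	8	8	323	109	15	ok	78C5-6;78E3-79A1
Df(3R)ED5177	7	7	462	105	16	ok	83B4;83B6
Df(3R)ED5780	13	13	61	22	4	ok	89E11;90C1
Df(3R)D605	8	8	274	85	15	ok	97E2;98A3-4
Df(3L)pbl-X1	5	5	780	30	19	ok	65F6;66B7-8
Df(3L)ZP1	5	5	968	81	21	ok	66A17-20;66C1-5
Df(3L)BSC8	7	7	687	56	17	ok	74D3-75A1;75B2-5
Df(3L)ED4858	13	13	566	23	13	ok	76D3;77C1
Df(3L)rdgC-co2	10	10	686	37	11	ok	77A1;77D1
Df(3L)ED4978	1	1	1712	69	27	ok	78D5;79A2
Df(3L)Ten-m-AL29	2	2	1079	64	19	ok	79C1-3;79E3-8
Df(3R)Tpl10	2	2	647	20	22	ok	83C1-2;84B1-2
Df(3R)GB104	1	1	189	2	1	ok	85D12;85E10
Df(3R)ED5559	3	3	270	0	0	ok	86E11;87B11
Df(3R)sbd105	16	16	1022	106	23	ok	88F9-89A1;89B9-10
Df(3R)ED5942	11	11	725	78	18	ok	91F12;92B3
Df(3R)BSC55	11	11	613	43	20	ok	94D2-10;94E1-6
Df(3R)mbc-30	11	11	181	8	1	ok	95A5-7;95C10-11
Df(3R)mbc-R1	14	14	1302	32	49	ok	95A5-7;95D6-11
Df(3R)Exel6202	13	13	837	64	29	ok	96D1;96D1
Df(3R)BSC42	14	14	1849	126	35	ok	98B1-2;98B3-5
Df(3R)3450	2	2	1003	42	28	ok	98E3;99A6-8
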