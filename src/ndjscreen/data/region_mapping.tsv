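region	deficiency	breakpoints	effect
77B	Df(3L)rdgC-co2	77A1;77D1	positive
77B	Df(3L)ED4858	76D3;77C1	positive
77B	Df(3L)Exel6136	77B2;77C6	positive
94E	Df(3R)BSC56	94E1-2;94F1-2	positive
94E	Df(3R)Exel6274	94E4;94E11	positive
94E	Df(3R)BSC55	94D2-10;94E1-6	negative
94E	Df(3R)Exel6193	94D3;94E4	negative
94E	Df(3R)ED6103	94D3;94E9	negative
94E	Df(3R)Exel6194	94F1;95A4	negative
98A	Df(3R)D605	97E2;98A3-4	positive
98A	Df(3R)ED6265	97E2;98A7	positive
98A	Df(3R)ED6255	97D2;97F1	negative
98A	Df(3R)Exel6206	97E1;97E5	negative
98A	Df(3R)ED6237	97E4;97E11	negative
98A	Df(3R)IR16	97F1-2;98A	negative
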