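position	A	C	G	T
1	0.288	0.097	0.052	0.563
2	0.451	0.021	0.052	0.476
3	0.236	0.028	0.028	0.708
4	0.253	0.007	0.097	0.642
5	0.052	0.000	0.000	0.948
6	0.038	0.007	0.003	0.951
7	0.160	0.073	0.007	0.760
8	0.969	0.000	0.000	0.031
9	0.087	0.177	0.000	0.736
10	0.288	0.056	0.576	0.080
11	0.066	0.000	0.017	0.917
12	0.000	0.000	0.000	1.000
13	0.000	0.007	0.000	0.993
14	0.517	0.000	0.014	0.469
15	0.021	0.056	0.708	0.215
16	0.076	0.076	0.295	0.552
17	0.104	0.125	0.045	0.726
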