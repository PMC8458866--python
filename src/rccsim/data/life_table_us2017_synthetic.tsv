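age	q_annual
62	0.009800
63	0.010716
64	0.011718
65	0.012814
66	0.014012
67	0.015322
68	0.016755
69	0.018321
70	0.020034
71	0.021908
72	0.023956
73	0.026196
74	0.028645
75	0.031324
76	0.034252
77	0.037455
78	0.040957
79	0.044786
80	0.048974
81	0.053553
82	0.058560
83	0.064035
84	0.070023
85	0.076570
86	0.083729
87	0.091558
88	0.100119
89	0.109480
90	0.119716
91	0.130909
92	0.143149
93	0.156534
94	0.171170
95	0.187174
96	0.204675
97	0.223812
98	0.244739
99	0.267622
100	0.292644
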