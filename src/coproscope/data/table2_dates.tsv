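sample	lab_code	cra	error	d13c	cal_older	cal_younger
A10164	Wk28344	694	30	-29.9	663	559
A10173	Wk28346	975	30	-29.1	920	772
A10144	Wk29439	997	26	-28.6	923	798
A10147	Wk28341	1000	30	-29.0	927	796
A10162	Wk28343	1060	30	-31.2	967	811
A10165	Wk28345	1879	30	-29.4	1865	1632
A10142	Wk28340	1915	30	-29.4	1875	1713
A10153	Wk29442	1959	25	-29.1	1927	1735
A10151	Wk29441	1964	25	-29.3	1929	1739
A10146	Wk29440	4520	28	-29.9	5290	4968
A10152	Wk28342	6310	31	-30.2	7266	7022
A10143	Wk29438	6368	31	-30.3	7315	7165
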