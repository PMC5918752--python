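# Confusion counts from a published evaluation of characteristic-based
# abstract screening on three environmental-health systematic reviews:
# Hamra 2014 (outdoor particulate matter and lung cancer, n=615, I=17),
# Johnson 2014 (PFOA and fetal growth, n=2470, I=17),
# Thayer 2013 (BPA exposure and obesity, n=1880, I=11).
# Only rows whose printed cells are internally consistent (they sum to the
# review's n and reproduce the printed precision/recall/work-saved) are
# kept; the remaining rows of the source table are typographically garbled.
review	rule	tp	fp	fn	tn
Hamra 2014	All4	5	5	12	593
Hamra 2014	Any3	12	24	5	574
Hamra 2014	Any2	17	89	0	509
Hamra 2014	PEO	11	17	6	581
Hamra 2014	PE	11	13	6	585
Hamra 2014	EO	17	65	0	533
Johnson 2014	Any3	14	12	3	2441
Johnson 2014	Any2	16	60	1	2393
Johnson 2014	EO	16	11	1	2442
Thayer 2013	All4	7	20	13	1840
Thayer 2013	Any3	9	83	2	1786
Thayer 2013	Any2	11	304	0	1565
Thayer 2013	PEO	7	116	4	1753
Thayer 2013	PE	14	45	6	1815
Thayer 2013	EO	11	195	0	1674
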