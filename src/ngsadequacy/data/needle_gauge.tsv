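gauge	inner_diameter_mm
14	1.60
15	1.37
16	1.19
17	1.07
18	0.84
19	0.69
20	0.60
21	0.51
22	0.41
23	0.34
24	0.31
25	0.26
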