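role	FaTCP11	FaPCL1-like	FaSCL8	rpkm_min	rpkm_max	rpkm_avg
PAL1	NA	0.79	NA	171	525	343
PAL2	0.81	0.76	0.72	84	207	155
C4H	NA	0.74	NA	34	172	91
4CL	0.78	0.67	NA	272	935	608
CHS1	0.78	0.72	0.80	500	1442	1079
CHS2	0.78	0.81	0.75	831	2518	1791
F3H	0.75	NA	0.69	661	2209	1570
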