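key	dH_kcal	dS_cal	provenance
init	0.0	0.0	unified98
init_5T/A	0.0	0.0	unified98
init_A/T	2.3	4.1	unified98
init_G/C	0.1	-2.8	unified98
init_allA/T	0.0	0.0	unified98
init_oneG/C	0.0	0.0	unified98
sym	0.0	-1.4	unified98
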