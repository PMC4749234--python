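key	dH_kcal	dS_cal	provenance
AZ	-4.0	-6.5	placeholder
CZ	-4.0	-6.5	placeholder
GZ	-4.0	-6.5	placeholder
TZ	-4.0	-6.5	placeholder
ZA	-4.0	-6.5	placeholder
ZC	-4.0	-6.5	placeholder
ZG	-4.0	-6.5	placeholder
ZT	-4.0	-6.5	placeholder
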