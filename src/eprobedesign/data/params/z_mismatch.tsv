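key	dH_kcal	dS_cal	provenance
NZ/AN	-3.6	-4.4	this-calibration
ZN/NA	-2.9	-3.2	this-calibration
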