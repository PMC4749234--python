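key	value
monovalent_M	0.05
divalent_M	0.0
dntp_M	0.0
scheme	santalucia1998-entropy
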