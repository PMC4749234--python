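key	dH_kcal	dS_cal	provenance
AA/TT	-7.9	-22.2	unified98
AT/TA	-7.2	-20.4	unified98
CA/GT	-8.5	-22.7	unified98
CG/GC	-10.6	-27.2	unified98
CT/GA	-7.8	-21.0	unified98
GA/CT	-8.2	-22.2	unified98
GC/CG	-9.8	-24.4	unified98
GG/CC	-8.0	-19.9	unified98
GT/CA	-8.4	-22.4	unified98
TA/AT	-7.2	-21.3	unified98
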