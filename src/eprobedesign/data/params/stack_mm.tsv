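key	dH_kcal	dS_cal	provenance
AA/TA	1.2	1.7	terminal-mm-lit
AA/TC	2.3	4.6	terminal-mm-lit
AA/TG	-0.6	-2.3	terminal-mm-lit
AC/TA	5.3	14.6	terminal-mm-lit
AC/TC	0.0	-4.4	terminal-mm-lit
AC/TT	0.7	0.2	terminal-mm-lit
AG/TA	-0.7	-2.3	terminal-mm-lit
AG/TG	-3.1	-9.5	terminal-mm-lit
AG/TT	1.0	0.9	terminal-mm-lit
AT/TC	-1.2	-6.2	terminal-mm-lit
AT/TG	-2.5	-8.3	terminal-mm-lit
AT/TT	-2.7	-10.8	terminal-mm-lit
CA/GA	-0.9	-4.2	terminal-mm-lit
CA/GC	1.9	3.7	terminal-mm-lit
CA/GG	-0.7	-2.3	terminal-mm-lit
CC/GA	0.6	-0.6	terminal-mm-lit
CC/GC	-1.5	-7.2	terminal-mm-lit
CC/GT	-0.8	-4.5	terminal-mm-lit
CG/GA	-4.0	-13.2	terminal-mm-lit
CG/GG	-4.9	-15.3	terminal-mm-lit
CG/GT	-4.1	-11.7	terminal-mm-lit
CT/GC	-1.5	-6.1	terminal-mm-lit
CT/GG	-2.8	-8.0	terminal-mm-lit
CT/GT	-5.0	-15.8	terminal-mm-lit
GA/CA	-2.9	-9.8	terminal-mm-lit
GA/CC	5.2	14.2	terminal-mm-lit
GA/CG	-0.6	-1.0	terminal-mm-lit
GC/CA	-0.7	-3.8	terminal-mm-lit
GC/CC	3.6	8.9	terminal-mm-lit
GC/CT	2.3	5.4	terminal-mm-lit
GG/CA	0.5	3.2	terminal-mm-lit
GG/CG	-6.0	-15.8	terminal-mm-lit
GG/CT	3.3	10.4	terminal-mm-lit
GG/TT	5.8	16.3	mismatch-lit
GT/CC	5.2	13.5	terminal-mm-lit
GT/CG	-4.4	-12.3	terminal-mm-lit
GT/CT	-2.2	-8.4	terminal-mm-lit
GT/TG	4.1	9.5	mismatch-lit
TA/AA	4.7	12.9	terminal-mm-lit
TA/AC	3.4	8.0	terminal-mm-lit
TA/AG	0.7	0.7	terminal-mm-lit
TC/AA	7.6	20.2	terminal-mm-lit
TC/AC	6.1	16.4	terminal-mm-lit
TC/AT	1.2	0.7	terminal-mm-lit
TG/AA	3.0	7.4	terminal-mm-lit
TG/AG	1.6	3.6	terminal-mm-lit
TG/AT	-0.1	-1.7	terminal-mm-lit
TG/GT	-1.4	-6.2	mismatch-lit
TT/AC	1.0	0.7	terminal-mm-lit
TT/AG	-1.3	-5.3	terminal-mm-lit
TT/AT	0.2	-1.5	terminal-mm-lit
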