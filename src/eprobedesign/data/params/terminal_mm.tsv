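key	dH_kcal	dS_cal	provenance
AA/TA	-3.1	-7.8	terminal-mm-lit
AA/TC	-1.6	-4.0	terminal-mm-lit
AA/TG	-1.9	-4.4	terminal-mm-lit
AC/TA	-1.8	-3.8	terminal-mm-lit
AC/TC	-0.1	0.5	terminal-mm-lit
AC/TT	-0.9	-1.7	terminal-mm-lit
AG/TA	-2.5	-5.9	terminal-mm-lit
AG/TG	-1.1	-2.1	terminal-mm-lit
AG/TT	-3.2	-8.7	terminal-mm-lit
AT/TC	-2.3	-6.3	terminal-mm-lit
AT/TG	-3.5	-9.4	terminal-mm-lit
AT/TT	-2.4	-6.5	terminal-mm-lit
CA/GA	-4.3	-10.7	terminal-mm-lit
CA/GC	-2.6	-5.9	terminal-mm-lit
CA/GG	-3.9	-9.6	terminal-mm-lit
CC/GA	-2.7	-6.0	terminal-mm-lit
CC/GC	-2.1	-5.1	terminal-mm-lit
CC/GT	-3.2	-8.0	terminal-mm-lit
CG/GA	-6.0	-15.5	terminal-mm-lit
CG/GG	-3.8	-9.5	terminal-mm-lit
CG/GT	-3.8	-9.0	terminal-mm-lit
CT/GC	-3.9	-10.6	terminal-mm-lit
CT/GG	-6.6	-18.7	terminal-mm-lit
CT/GT	-6.1	-16.9	terminal-mm-lit
GA/CA	-8.0	-22.5	terminal-mm-lit
GA/CC	-5.0	-13.8	terminal-mm-lit
GA/CG	-4.3	-11.1	terminal-mm-lit
GC/CA	-3.2	-7.1	terminal-mm-lit
GC/CC	-3.9	-10.6	terminal-mm-lit
GC/CT	-4.9	-13.5	terminal-mm-lit
GG/CA	-4.6	-11.4	terminal-mm-lit
GG/CG	-0.7	-19.2	terminal-mm-lit
GG/CT	-5.7	-15.9	terminal-mm-lit
GT/CC	-3.0	-7.8	terminal-mm-lit
GT/CG	-5.9	-16.1	terminal-mm-lit
GT/CT	-7.4	-21.2	terminal-mm-lit
TA/AA	-2.5	-6.3	terminal-mm-lit
TA/AC	-2.3	-5.9	terminal-mm-lit
TA/AG	-2.0	-4.7	terminal-mm-lit
TC/AA	-2.7	-7.0	terminal-mm-lit
TC/AC	-0.7	-1.3	terminal-mm-lit
TC/AT	-2.5	-6.3	terminal-mm-lit
TG/AA	-2.4	-5.8	terminal-mm-lit
TG/AG	-1.1	-2.7	terminal-mm-lit
TG/AT	-3.9	-10.5	terminal-mm-lit
TT/AC	-0.7	-1.2	terminal-mm-lit
TT/AG	-3.6	-9.8	terminal-mm-lit
TT/AT	-3.2	-8.9	terminal-mm-lit
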