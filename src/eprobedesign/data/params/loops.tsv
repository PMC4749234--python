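loop_len	dS_penalty
3	-11.28486216346929
4	-11.28486216346929
5	-10.640012896985331
6	-12.896985329679188
7	-13.219409962921167
8	-13.219409962921167
9	-13.541834596163147
10	-13.864259229405128
12	-14.509108495889087
14	-14.831533129131067
16	-15.153957762373047
18	-15.476382395615026
20	-15.798807028857006
25	-16.766080928582944
30	-17.410930195066904
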