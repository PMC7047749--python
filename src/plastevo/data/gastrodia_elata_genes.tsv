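gene	status
accD	P
clpP	P
matK	P
rpl2	P
rpl14	P
rpl16	P
rpl20	P
rpl36	P
rps2	P
rps3	P
rps4	P
rps7	P
rps8	P
rps11	P
rps12	P
rps14	P
rps18	P
rps19	P
rrn5	P
rrn16	P
rrn23	P
ycf1	P
ycf2	P
psaI	PSEUDO
psbK	PSEUDO
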