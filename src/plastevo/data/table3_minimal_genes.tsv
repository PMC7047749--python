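taxon	accD	clpP	rpl2	rpl14	rpl16	rpl36	rps2	rps3	rps4	rps7	rps8	rps11	rps14	rps18	rps19	rrn5	rrn16	rrn23	trnC-GCA	trnfM-CAU
Epipogium aphyllum	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Epipogium roseum	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Gastrodia elata 1	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Gastrodia elata 2	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Lecanorchis japonica	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Lecanorchis kiusiana	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
Rhizanthella gardneri	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P	P
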