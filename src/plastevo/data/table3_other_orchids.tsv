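gene	n_present	n_total	exceptions
accD	116	117	Vanilla aphylla (Pseudogene)
clpP	117	117	
rpl2	113	117	Anoectochilus emeiensis (Absent), Goodyera procera (Absent), G. schlechtendaliana (Absent), G. velutina (Absent)
rpl14	117	117	
rpl16	117	117	
rpl36	117	117	
rps2	117	117	
rps3	117	117	
rps4	117	117	
rps7	117	117	
rps8	117	117	
rps11	117	117	
rps14	117	117	
rps18	115	117	Neottia nidus-avis (Absent), Goodyera procera (Absent)
rps19	116	117	Goodyera procera (Absent)
rrn5	117	117	
rrn16	117	117	
rrn23	117	117	
trnC-GCA	117	117	
trnfM-CAU	115	117	Ophrys fusca subsp. iricolor (Absent) Ophrys sphegodes (Absent)
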