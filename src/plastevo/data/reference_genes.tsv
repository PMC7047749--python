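name	gene_class	kind	ref_length	n_exons	region	strand
trnH-GUG	trn	tRNA	74	1	LSC	-1
psbA	psb	CDS	1062	1	LSC	-1
trnK-UUU	trn	tRNA	72	2	LSC	-1
matK	other	CDS	1530	1	LSC	-1
rps16	rps	CDS	273	2	LSC	-1
trnQ-UUG	trn	tRNA	72	1	LSC	-1
psbK	psb	CDS	186	1	LSC	-1
psbI	psb	CDS	111	1	LSC	-1
trnS-GCU	trn	tRNA	88	1	LSC	-1
trnG-UCC	trn	tRNA	71	2	LSC	1
trnR-UCU	trn	tRNA	72	1	LSC	1
atpA	atp	CDS	1524	1	LSC	-1
atpF	atp	CDS	555	2	LSC	-1
atpH	atp	CDS	246	1	LSC	-1
atpI	atp	CDS	744	1	LSC	-1
rps2	rps	CDS	711	1	LSC	-1
rpoC2	rpo	CDS	4158	1	LSC	-1
rpoC1	rpo	CDS	2046	2	LSC	-1
rpoB	rpo	CDS	3213	1	LSC	-1
trnC-GCA	trn	tRNA	71	1	LSC	1
petN	pet	CDS	90	1	LSC	1
psbM	psb	CDS	105	1	LSC	-1
trnD-GUC	trn	tRNA	74	1	LSC	-1
trnY-GUA	trn	tRNA	84	1	LSC	-1
trnE-UUC	trn	tRNA	73	1	LSC	-1
trnT-GGU	trn	tRNA	72	1	LSC	1
psbD	psb	CDS	1062	1	LSC	1
psbC	psb	CDS	1386	1	LSC	1
trnS-UGA	trn	tRNA	93	1	LSC	-1
psbZ	psb	CDS	189	1	LSC	1
trnG-GCC	trn	tRNA	71	1	LSC	1
trnfM-CAU	trn	tRNA	74	1	LSC	-1
rps14	rps	CDS	303	1	LSC	-1
psaB	psa	CDS	2205	1	LSC	-1
psaA	psa	CDS	2253	1	LSC	-1
ycf3	other	CDS	507	3	LSC	-1
trnS-GGA	trn	tRNA	87	1	LSC	-1
rps4	rps	CDS	606	1	LSC	-1
trnT-UGU	trn	tRNA	73	1	LSC	-1
trnL-UAA	trn	tRNA	85	2	LSC	1
trnF-GAA	trn	tRNA	73	1	LSC	1
ndhJ	ndh	CDS	477	1	LSC	-1
ndhK	ndh	CDS	678	1	LSC	-1
ndhC	ndh	CDS	363	1	LSC	-1
trnV-UAC	trn	tRNA	73	2	LSC	-1
trnM-CAU	trn	tRNA	73	1	LSC	1
atpE	atp	CDS	402	1	LSC	-1
atpB	atp	CDS	1497	1	LSC	-1
rbcL	other	CDS	1434	1	LSC	1
accD	other	CDS	1497	1	LSC	1
psaI	psa	CDS	111	1	LSC	1
ycf4	other	CDS	555	1	LSC	1
cemA	other	CDS	690	1	LSC	1
petA	pet	CDS	963	1	LSC	1
psbJ	psb	CDS	123	1	LSC	-1
psbL	psb	CDS	117	1	LSC	-1
psbF	psb	CDS	120	1	LSC	-1
psbE	psb	CDS	252	1	LSC	-1
petL	pet	CDS	96	1	LSC	1
petG	pet	CDS	114	1	LSC	1
trnW-CCA	trn	tRNA	74	1	LSC	-1
trnP-UGG	trn	tRNA	74	1	LSC	-1
psaJ	psa	CDS	135	1	LSC	1
rpl33	rpl	CDS	201	1	LSC	1
rps18	rps	CDS	306	1	LSC	1
rpl20	rpl	CDS	354	1	LSC	-1
rps12	rps	CDS	372	2	LSC	-1
clpP	other	CDS	591	3	LSC	-1
psbB	psb	CDS	1527	1	LSC	1
psbT	psb	CDS	108	1	LSC	1
psbN	psb	CDS	132	1	LSC	-1
psbH	psb	CDS	222	1	LSC	1
petB	pet	CDS	648	2	LSC	1
petD	pet	CDS	543	2	LSC	1
rpoA	rpo	CDS	1014	1	LSC	-1
rps11	rps	CDS	417	1	LSC	-1
rpl36	rpl	CDS	114	1	LSC	-1
infA	other	CDS	234	1	LSC	-1
rps8	rps	CDS	405	1	LSC	-1
rpl14	rpl	CDS	369	1	LSC	-1
rpl16	rpl	CDS	408	2	LSC	-1
rps3	rps	CDS	657	1	LSC	-1
rpl22	rpl	CDS	462	1	LSC	-1
rps19	rps	CDS	279	1	LSC	-1
rpl2	rpl	CDS	828	2	IR	-1
rpl23	rpl	CDS	282	1	IR	-1
trnI-CAU	trn	tRNA	74	1	IR	-1
ycf2	other	CDS	6840	1	IR	1
trnL-CAA	trn	tRNA	81	1	IR	-1
ndhB	ndh	CDS	1533	2	IR	-1
rps7	rps	CDS	468	1	IR	-1
trnV-GAC	trn	tRNA	72	1	IR	1
rrn16	rrn	rRNA	1490	1	IR	1
trnI-GAU	trn	tRNA	72	2	IR	1
trnA-UGC	trn	tRNA	73	2	IR	1
rrn23	rrn	rRNA	2810	1	IR	1
rrn4.5	rrn	rRNA	103	1	IR	1
rrn5	rrn	rRNA	121	1	IR	1
trnR-ACG	trn	tRNA	74	1	IR	1
trnN-GUU	trn	tRNA	72	1	IR	-1
ndhF	ndh	CDS	2241	1	SSC	-1
rpl32	rpl	CDS	174	1	SSC	1
trnL-UAG	trn	tRNA	80	1	SSC	1
ccsA	other	CDS	966	1	SSC	1
ndhD	ndh	CDS	1503	1	SSC	-1
psaC	psa	CDS	246	1	SSC	-1
ndhE	ndh	CDS	306	1	SSC	-1
ndhG	ndh	CDS	531	1	SSC	-1
ndhI	ndh	CDS	543	1	SSC	-1
ndhA	ndh	CDS	1092	2	SSC	-1
ndhH	ndh	CDS	1182	1	SSC	-1
rps15	rps	CDS	273	1	SSC	-1
ycf1	other	CDS	5400	1	SSC	1
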