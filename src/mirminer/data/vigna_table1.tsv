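name	gene_id	source	sequence	nm	lm	lp	location	au_fraction	mfei
vun-MIR156a	146512093	GSS	UGACAGAAGAUAGAGAGCAC	0	20	100	5	0.58	1.06
vun-MIR156b	146512093	GSS	CAGAAGAUAGAGAGCACAGA	2	20	92	5	0.58	1.06
vun-MIR156c	146512093	GSS	UUGACAGAAGAUAGAGAGCAC	0	21	100	5	0.59	1.06
vun-MIR156d	146512093	GSS	UGACAGAAGAUAGAGAGCACA	1	21	100	5	0.58	1.06
vun-MIR156e	190469749	EST	CAGAAGAUAGAGAGCACAGA	2	20	77	5	0.58	1.18
vun-MIR156f	190510876	EST	UGACAGAAGAGAGUGAGCACA	0	21	82	5	0.55	1.09
vun-MIR156g	190510876	EST	UUGACAGAAGAGAGUGAGCAC	3	21	84	5	0.55	1.07
vun-MIR156h	190510876	EST	UGACAGAAGAGAGUGAGCAC	0	20	82	5	0.55	1.09
vun-MIR156i	190416464	EST	UGACAGAAGAGAGUGAGCACA	0	21	82	5	0.57	1.29
vun-MIR156j	190416464	EST	UUGACAGAAGAGAGUGAGCAC	3	21	84	5	0.58	1.30
vun-MIR156k	190416464	EST	UGACAGAAGAGAGUGAGCAC	0	20	82	5	0.57	1.29
vun-MIR157a	190469749	EST	UUGACAGAAGAUAGAGAGCAC	1	21	84	5	0.60	1.32
vun-MIR157b	190469749	EST	UGACAGAAGAUAGAGAGCAC	0	20	84	5	0.60	1.31
vun-MIR157c	190469749	EST	UGACAGAAGAUAGAGAGCACA	1	21	84	5	0.60	1.31
vun-MIR159	182406416	EST	CUUGGACUGAAGGGAGCUCCU	1	21	186	3	0.60	1.00
vun-MIR160a	190509770	EST	UGCCUGGCUCCCUGUAUGCCA	0	21	81	5	0.48	1.05
vun-MIR160b	190509770	EST	UGCCUGGCUCCCUGUAUGCC	0	20	81	5	0.48	1.05
vun-MIR164	146508076	GSS	UGGAGAAGCAGGGCACGUGCA	0	21	68	5	0.41	0.90
vun-MIR169a	190499818	EST	CAGCCAAGGAUGACUUGCCGGC	2	22	76	5	0.46	1.04
vun-MIR169b	190499818	EST	CAGCCAAGGAUGACUUGCCGG	0	21	76	5	0.46	1.04
vun-MIR169c	190499818	EST	GCAGCCAAGGAUGACUUGCCG	1	21	77	5	0.46	1.02
vun-MIR172a	190415307	EST	AGAAUCUUGAUGAUGCUGCAUCAG	2	24	109	3	0.55	1.02
vun-MIR172b	190415307	EST	UGAAUCUUGAUGAUGCUACAU	0	21	101	3	0.57	0.89
vun-MIR172c	190415307	EST	AGAAUCUUGAUGAUGCUGCAU	0	21	101	3	0.57	1.03
vun-MIR172d	190415307	EST	UGAAUCUUGAUGAUGCUACA	2	20	100	3	0.57	0.87
vun-MIR172e	190415307	EST	AGAAUCUUGAUGAUGCUGCA	1	20	101	3	0.56	0.99
vun-MIR319a	182650666	EST	UUGGACUGAAGGGAGCUCCCU	0	21	172	3	0.58	0.99
vun-MIR319b	182650666	EST	CUUGGACUGAAGGGAGCUCCC	0	21	174	3	0.59	1.03
vun-MIR319c	182650666	EST	UUGGACUGAAGGGAGCUCCC	0	20	174	3	0.59	1.03
vun-MIR319d	182650666	EST	CUUGGACUGAAGGGAGCUCC	0	20	167	3	0.58	1.01
vun-MIR319e	182650666	EST	UUGGACUGAAGGGAGCUCC	0	19	167	3	0.58	1.01
vun-MIR319f	182406416	EST	UUGGACUGAAGGGAGCUCCUU	0	21	188	3	0.59	1.00
vun-MIR319g	182406416	EST	CUUGGACUGAAGGGAGCUCC	0	20	184	3	0.58	1.00
vun-MIR319h	182406416	EST	UUGGACUGAAGGGAGCUCCU	0	20	186	3	0.59	1.00
vun-MIR319i	182406416	EST	UUGGACUGAAGGGAGCUCC	0	19	184	3	0.58	0.98
vun-MIR395a	146525281	GSS	CUGAAGUGUUUGGGGGAACUCC	0	22	81	3	0.59	1.04
vun-MIR395b	146525281	GSS	CUGAAGUGUUUGGGGGAACUC	0	21	80	3	0.60	1.04
vun-MIR399a	182643512	EST	UGCCAAAGGAGAAUUGCCCUG	0	21	77	3	0.52	0.91
vun-MIR399b	182643512	EST	UGCCAAAGGAGAAUUGCCC	0	19	77	3	0.52	0.91
vun-MIR399c	182648023	EST	UGCCAAAGGAGAGUUGCCCUG	0	21	73	3	0.56	1.16
vun-MIR399d	182648023	EST	UGCCAAAGGAGAGUUGCCC	1	19	69	3	0.55	1.11
vun-MIR482	146504713	GSS	UCUUCCCAAUUCCGCCCAUUCCUA	0	24	80	3	0.56	0.96
vun-MIR1507a	182400468	EST	UCUCAUUCCAUACAUCGUCUGA	0	22	88	3	0.53	1.03
vun-MIR1507b	182400468	EST	UCUCAUUCCAUACAUCGUCUG	0	21	87	3	0.53	1.03
vun-MIR1507c	190551234	EST	UCUCAUUCCAUACAUCGUCUGA	0	22	88	3	0.55	1.18
vun-MIR1507d	190551234	EST	UCUCAUUCCAUACAUCGUCUG	0	21	87	3	0.54	1.16
vun-MIR2118	190540631	EST	UUGCCGAUUCCACCCAUUCCUA	1	22	75	3	0.57	1.11
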