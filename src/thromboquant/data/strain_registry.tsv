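strain_id	gene	protein	modification	background	database_id	delta_sac	thrombosis	bleeding	reference
Ano1	Ano1	Anoctamin-1	PF4-Cre Ano1	C57Bl/6	07	o	nd	nd	B18
Ano6	Ano6	Anoctamin-6	Ano6^Gt(AW0382)	C57Bl/6	07	o	nd	up	B18
Anxa1	Anxa1	Annexin A1	PF4-Cre Anxa1	C57Bl/6	22	o	nd	nd	B23
Apoe	Apoe	Apolipoprotein E	Apoe^tm1Unc	C57Bl/6	22	up	nd	nd	B23
Bnip2	Bnip2	BCL2-interacting protein 2	Bnip2^tm1a	C57Bl/6N	21	o	nd	nd	B23
Capn1	Capn1	Calpain-1	Capn1^tm1Ahc	C57Bl/6	10	up	down	nd	B27;B28
Cd36	Cd36	CD36	Cd36^tm1Mfe	C57Bl/6	14	o	down	o	B29;B30
Cdc42	Cdc42	Small GTPase CDC42	PF4-Cre Cdc42	C57Bl/6 x 129SV	20	o	up	up	B31
Clec1b	Clec1b	CLEC2	INU1 Ab	C57Bl/6	19	down	down	up	B20
Csk	Csk	Tyrosine kinase CSK	PF4-Cre Csk tm1Tara	C57Bl/6	23	down	down	up	B32
Dlg4	Dlg4	Scaffold protein DLG4	Dlg4^tm1a	C57Bl/6N	21	o	nd	nd	B23
Dusp3	Dusp3	Protein phosphatase DUSP3	Dusp3^tm1Srah	C57Bl/6	11	down	down	o	B33
Fcer1g	Fcer1g	FcR gamma-chain	Fcer1g^tm1Rav	C57Bl/6 x 129SV	04	down	down	nd	B34;B35
Fpr2	Fpr2	Formyl peptide receptor-2	Fpr2^Tg(ACTB)#Jimw	C57Bl/6	22	up	nd	nd	B23
Gnaq	Gnaq	Gq alpha-subunit	Gnaq^tm1Soff	C57Bl/6 x 129SV	04	down	down	up	B34;B36
Gp6	Gp6	GPVI	Gp6^tm1Beni	C57Bl/6	03	down	down	o	B37;B38
Gp6/Clec1b	Gp6/Clec1b	GPVI/CLEC2	JAQ1+INU1 Ab	C57Bl/6	03	nd	down	up	B38
Grm8	Grm8	Glutamate metabotropic receptor 8	Grm8^tm1a	C57Bl/6N	21	o	nd	nd	B23
Ifnar1	Ifnar1	Interferon receptor 1	Ifnar1^tm1a	C57Bl/6N	21	down	nd	nd	B23
Itga2	Itga2	Integrin alpha2	LoxP-Cre Itga2	C57Bl/6 x 129SV	05	down	down	o	B5;B39
Itgb1	Itgb1	Integrin beta1	Mx-Cre Itgb1	C57Bl/6 x 129SV	04	down	o	o	B5;B34;B40
Kcnn4	Kcnn4	K-activated Ca channel-4	Kcnn4^tm1Rklr	C57Bl/6 x 129SV	16	o	nd	nd	B18
Mpig6b	Mpig6b	Receptor G6B-b	Mpig6b^tm1.1Arte	C57Bl/6	24	down	nd	up	B41
Orai1	Orai1	Calcium channel ORAI1	BMC Orai1-/-	C57Bl/6	01	down	down	o-up	B42;B43
Pik3cg	Pik3cg	PI 3-kinase gamma	Pik3cg^tm1Wym	129SV	13	down	down	o	B44;B45
Plcg2-GOF	Plcg2	Phospholipase C-gamma2 (GOF)	Plcg2^Ali5	C3HeB/FeJ	12	up	up	nd	B46
Pld1	Pld1	Phospholipase D1	Pld1^tm3Mafr	C57Bl/6	02	o	down	o	B14
Prkca	Prkca	Protein kinase C-alpha	Prkca^Myh6/tetO/1Jmk	C57Bl/6	06	down	down	o	B47;B48
Prkcd	Prkcd	Protein kinase C-delta	Prkcd^tm1Kin	C57Bl/6	06	up	o	nd	B47;B49
Prkcq	Prkcq	Protein kinase C-theta	Prkcq^tm1Litt	C57Bl/6	06	up	nd	nd	B47
Prkd2	Prkd2	Protein kinase D2	Prkd2^tm1.1Daca	C57Bl/6	17	down	nd	o	B50
Ptprj	Ptprj	Phosphatase CD148	PF4-Cre Ptprj^tm1.1Weis	C57Bl/6	23	down	down	o	B32
Rac1	Rac1	Small GTPase RAC1	Mx-Cre Rac1	C57Bl/6	08	down	down	up	B51
Rhoa	Rhoa	Small GTPase RHO-A	PF4-Cre Rhoa	C57Bl/6 x 129SV	08	o	down	up	B13
Stim1	Stim1	Regulator STIM1	BMC Stim1-/-	C57Bl/6	01	down	down	up	B42;B52
Stim2	Stim2	Regulator STIM2	Stim2^tm1Beni	C57Bl/6	01	o	nd	nd	B42
Syk	Syk	Tyrosine kinase SYK	PF4-Cre Syk^tm1(syk)Spwa	C57Bl/6	09	nd	down	up	B53
Vps13a	Vps13a	Vacuolar sorting protein VPS13A	Vps13a^tm1a	C57Bl/6N	21	down	nd	nd	B23
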