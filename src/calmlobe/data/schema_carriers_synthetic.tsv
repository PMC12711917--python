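gene	protein_change	cohort	carrier_id	mpc	cadd
CALM1	S82R	SCZ	scz01	2.4	25.1
CALM1	R107C	SCZ	scz02	2.1	27.3
CALM1	R107C	SCZ	scz03	2.1	27.3
CALM2	I131L	SCZ	scz04	1.6	22.4
CALM2	N138S	SCZ	scz05	1.8	24.0
CALM2	Y139C	SCZ	scz06	2.6	26.8
CALM3	Q144E	SCZ	scz07	1.5	21.9
CALM1	R87Q	control	ctrl01	1.7	23.5
CALM2	V109I	control	ctrl02	0.9	18.2
CALM3	D123E	control	ctrl03	1.2	19.6
CALM3	I131T	control	ctrl04	1.9	23.1
CALM3	M146V	control	ctrl05	0.8	17.4
CALM1	T27S	control	ctrl06	2.2	24.6
CALM1	T35I	control	ctrl07	2.3	25.0
CALM2	I28V	control	ctrl08	1.1	18.9
CALM2	I28V	control	ctrl09	1.1	18.9
CALM2	K22R	control	ctrl10	0.7	16.2
CALM2	D51N	control	ctrl11	1.4	21.0
CALM3	A2T	control	ctrl12	0.5	12.3
CALM3	Q9H	control	ctrl13	0.6	14.8
CALM3	I10V	control	ctrl14	0.9	16.9
CALM3	K14R	control	ctrl15	0.7	15.5
CALM3	S18N	control	ctrl16	1.0	17.8
CALM3	T30A	control	ctrl17	1.3	20.2
CALM3	R38Q	control	ctrl18	2.0	23.9
CALM3	N43S	control	ctrl19	2.1	24.2
CALM3	Q50H	control	ctrl20	1.2	19.1
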