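gene	variant	aa_change	category
MT-ND4	m.11778G>A	R340H	primary
MT-ND1	m.3460G>A	A52T	primary
MT-ND1	m.3866T>C	I187T	primary
MT-ND6	m.14484T>C	M64V	primary
MT-ND1	m.3376G>A	E24K	primary
MT-ND1	m.3635G>A	S110N	primary
MT-ND1	m.3697G>A	G131S	primary
MT-ND1	m.3700G>A	A112T	primary
MT-ND1	m.3733G>A	E143K	primary
MT-ND1	m.4171C>A	L289M	primary
MT-ND3	m.10197G>A	A47T	primary
MT-ND4L	m.10663T>C	V65A	primary
MT-ND5	m.12338T>C	M1T	primary
MT-ND5	m.13051G>A	G239S	primary
MT-ND5	m.13094T>C	V253A	primary
MT-ND6	m.14459G>A	A72V	primary
MT-ND6	m.14482C>A	M64I	primary
MT-ND6	m.14482C>G	M64I	primary
MT-ND6	m.14495A>G	L60S	primary
MT-ND6	m.14502T>C	I58V	primary
MT-ND6	m.14568C>T	G36S	primary
MT-ND1	m.3394T>C	Y30H	candidate
MT-ND1	m.3472T>C	F56L	candidate
MT-ND1	m.4025C>T	T240M	candidate
MT-ND1	m.4160T>C	L285P	candidate
MT-TM	m.4435A>G		candidate
MT-ND2	m.4640C>A	I57M	candidate
MT-ND2	m.5244G>A	G259S	candidate
MT-ATP6	m.9101T>C	I192T	candidate
MT-CO3	m.9804G>A	A200T	candidate
MT-ND3	m.10237T>C	I60T	candidate
MT-ND4	m.11253T>C	I165T	candidate
MT-ND4	m.11696G>A	V312I	candidate
MT-ND5	m.12811T>C	Y159H	candidate
MT-ND5	m.12848C>T	A171V	candidate
MT-ND5	m.13637A>G	Q434R	candidate
MT-ND5	m.13730G>A	G465E	candidate
MT-ND6	m.14279G>A	S132L	candidate
MT-ND6	m.14325T>C	N117D	candidate
MT-ND6	m.14498T>C	Y59C	candidate
MT-ND6	m.14596A>T	I26M	candidate
MT-TE	m.14693A>G		candidate
MT-CYB	m.14831G>A	A29T	candidate
MT-TT	m.15927G>A		known_MT_TT
MT-TT	m.15951A>G		known_MT_TT
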