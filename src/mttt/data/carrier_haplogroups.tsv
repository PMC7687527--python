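subject_id	subgroup	variant	haplogroup
WZ1001	putative	m.15900T>C	H2
WZ1002	putative	m.15901A>G	D4
WZ1003	putative	m.15908T>C	F4
WZ1004	putative	m.15924A>G	D4e1a
WZ1005	putative	m.15924A>G	F1a1
WZ1006	putative	m.15924A>G	D4e1a
WZ1007	putative	m.15924A>G	D4e1a
WZ1008	putative	m.15924A>G	F1a'c
WZ1009	putative	m.15924A>G	D4e1a
WZ1010	putative	m.15924A>G	D4e1a
WZ1011	putative	m.15924A>G	F1a1
WZ1012	putative	m.15924A>G	B4
WZ1013	putative	m.15928G>A	M7b
WZ1014	putative	m.15928G>A	Y1
WZ1015	putative	m.15928G>A	Z
WZ1016	putative	m.15931A>C	A
WZ1017	putative	m.15940DelT	Z
WZ1018	putative	m.15943T>C	F3a
WZ1019	putative	m.15943T>C	D4
WZ1020	putative	m.15949G>A	F1a'c
WZ2101	m.15951A>G	m.15951A>G	D4
WZ2102	m.15951A>G	m.15951A>G	D4
WZ2103	m.15951A>G	m.15951A>G	D
WZ2104	m.15951A>G	m.15951A>G	D
WZ2201	m.15927G>A	m.15927G>A	B4
WZ2202	m.15927G>A	m.15927G>A	B4
WZ2203	m.15927G>A	m.15927G>A	B
WZ2204	m.15927G>A	m.15927G>A	B
WZ2205	m.15927G>A	m.15927G>A	B
WZ2206	m.15927G>A	m.15927G>A	G2
WZ2207	m.15927G>A	m.15927G>A	G
WZ2208	m.15927G>A	m.15927G>A	F
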